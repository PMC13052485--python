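"""Delimited-text spectra tables and cohort round-tripping.

A cohort on disk is a pair (optionally a trio) of UTF-8 TSV files:

* ``<stem>.spectra.tsv`` — header ``sample_id`` followed by the wavenumber
  grid (strictly increasing, cm^-1); one row per measurement.
* ``<stem>.meta.tsv`` — columns ``sample_id, patient_id, label, domain,
  n_accumulations``; every spectra row must have a metadata row.
* ``<stem>.accumulations.tsv`` — written only when raw accumulation
  matrices are present: columns ``sample_id, accumulation_index`` followed
  by the grid.

Floats are serialized with Python's shortest round-trip ``repr``, so a
write/read cycle reproduces values bit for bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cohort import UNKNOWN_LABEL, Cohort, Spectrum

__all__ = ["write_spectra", "read_spectra"]


def _fmt(value: float) -> str:
    return repr(float(value))


def _paths(path) -> tuple[Path, Path, Path]:
    stem = Path(path)
    for suffix in (".spectra", ".meta", ".accumulations"):
        if stem.name.endswith(suffix + ".tsv"):
            stem = stem.with_name(stem.name[: -len(suffix + ".tsv")])
            break
    else:
        if stem.suffix == ".tsv":
            stem = stem.with_suffix("")
    base = stem.parent / stem.name
    return (
        base.with_name(base.name + ".spectra.tsv"),
        base.with_name(base.name + ".meta.tsv"),
        base.with_name(base.name + ".accumulations.tsv"),
    )


def write_spectra(cohort: Cohort, path, include_accumulations: bool = True) -> None:
    """Serialize a cohort; ``path`` is the file stem (suffixes are added)."""
    spath, mpath, apath = _paths(path)
    spath.parent.mkdir(parents=True, exist_ok=True)
    wn = cohort.wavenumbers
    header = "sample_id\t" + "\t".join(_fmt(w) for w in wn)

    with open(spath, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for s in cohort.spectra:
            fh.write(s.sample_id + "\t" + "\t".join(_fmt(v) for v in s.intensities) + "\n")

    with open(mpath, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpatient_id\tlabel\tdomain\tn_accumulations\n")
        for s in cohort.spectra:
            n_acc = 0 if s.accumulations is None else s.accumulations.shape[0]
            fh.write(
                f"{s.sample_id}\t{s.patient_id}\t{s.label}\t{s.domain}\t{n_acc}\n"
            )

    has_acc = include_accumulations and any(s.accumulations is not None for s in cohort.spectra)
    if has_acc:
        with open(apath, "w", encoding="utf-8") as fh:
            fh.write("sample_id\taccumulation_index\t" + "\t".join(_fmt(w) for w in wn) + "\n")
            for s in cohort.spectra:
                if s.accumulations is None:
                    continue
                for i, row in enumerate(s.accumulations):
                    fh.write(
                        f"{s.sample_id}\t{i}\t" + "\t".join(_fmt(v) for v in row) + "\n"
                    )
    elif apath.exists():
        apath.unlink()


def _parse_label(text: str, line_no: int):
    if text == UNKNOWN_LABEL:
        return UNKNOWN_LABEL
    if text in ("0", "1"):
        return int(text)
    raise ValueError(
        f"metadata line {line_no}: label must be 0, 1 or {UNKNOWN_LABEL!r}, got {text!r}"
    )


def read_spectra(path) -> Cohort:
    """Read a cohort written by :func:`write_spectra`."""
    spath, mpath, apath = _paths(path)
    with open(spath, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "sample_id":
            raise ValueError(f"{spath}: first column must be sample_id, got {header[0]!r}")
        try:
            wn = np.array([float(h) for h in header[1:]])
        except ValueError as exc:
            raise ValueError(f"{spath}: non-numeric wavenumber in header: {exc}") from exc
        if wn.size >= 2 and not np.all(np.diff(wn) > 0):
            raise ValueError(f"{spath}: wavenumber header must be strictly increasing")
        rows: dict[str, np.ndarray] = {}
        order: list[str] = []
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != wn.size + 1:
                raise ValueError(
                    f"{spath} line {line_no}: expected {wn.size + 1} columns, got {len(parts)}"
                )
            try:
                rows[parts[0]] = np.array([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{spath} line {line_no}: bad value: {exc}") from exc
            order.append(parts[0])

    meta: dict[str, dict] = {}
    with open(mpath, encoding="utf-8") as fh:
        mheader = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "patient_id", "label", "domain", "n_accumulations"]
        if mheader != expected:
            raise ValueError(f"{mpath}: expected columns {expected}, got {mheader}")
        for line_no, line in enumerate(fh, start=2):
            sid, pid, label, domain, n_acc = line.rstrip("\n").split("\t")
            meta[sid] = {
                "patient_id": pid,
                "label": _parse_label(label, line_no),
                "domain": domain,
            }

    missing = [sid for sid in order if sid not in meta]
    if missing:
        raise ValueError(f"{mpath}: metadata rows missing for sample_ids {missing}")

    accumulations: dict[str, list[np.ndarray]] = {}
    if apath.exists():
        with open(apath, encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                accumulations.setdefault(parts[0], []).append(
                    np.array([float(v) for v in parts[2:]])
                )

    spectra = []
    domain = ""
    for sid in order:
        m = meta[sid]
        domain = m["domain"] or domain
        spectra.append(
            Spectrum(
                wavenumbers=wn,
                intensities=rows[sid],
                patient_id=m["patient_id"],
                sample_id=sid,
                label=m["label"],
                domain=m["domain"],
                accumulations=np.stack(accumulations[sid]) if sid in accumulations else None,
            )
        )
    return Cohort(spectra, domain=domain)
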