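"""Core data containers: a single Raman measurement and a patient-grouped cohort.

A :class:`Spectrum` is one measurement site: a strictly increasing wavenumber
grid (cm^-1), an intensity vector (arbitrary units), acquisition metadata and
optionally the raw accumulation matrix the detector produced before averaging.
A :class:`Cohort` groups labelled spectra of one acquisition domain (an organ /
instrument combination) and knows which patient each measurement came from,
which is what leave-one-patient-out evaluation needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Spectrum", "Cohort", "UNKNOWN_LABEL"]

#: Sentinel label for measurements without histopathology ground truth.
UNKNOWN_LABEL = "unknown"


@dataclass
class Spectrum:
    """One Raman measurement on a shared wavenumber grid.

    Parameters
    ----------
    wavenumbers:
        Strictly increasing Raman-shift grid in cm^-1.
    intensities:
        Intensity vector, same length as ``wavenumbers`` (a.u.).
    patient_id, sample_id:
        Identifiers; every measurement must be attributable to a patient.
    label:
        ``0`` (normal), ``1`` (cancer) or :data:`UNKNOWN_LABEL`.
    domain:
        Free-text tag of the acquisition domain (e.g. ``"prostate_target"``).
    accumulations:
        Optional raw matrix of shape ``(n_accumulations, n_points)`` before
        cosmic-ray removal and averaging.
    meta:
        Mutable dict of provenance notes (processing steps applied, flags).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    patient_id: str
    sample_id: str
    label: object = UNKNOWN_LABEL
    domain: str = ""
    accumulations: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.label not in (0, 1, UNKNOWN_LABEL):
            raise ValueError(f"label must be 0, 1 or {UNKNOWN_LABEL!r}, got {self.label!r}")
        if self.accumulations is not None:
            self.accumulations = np.asarray(self.accumulations, dtype=float)
            if self.accumulations.ndim != 2:
                raise ValueError("accumulations must be a 2-D matrix")
            if self.accumulations.shape[1] != self.wavenumbers.size:
                raise ValueError("accumulation rows must match the wavenumber grid")

    @property
    def n_points(self) -> int:
        return int(self.wavenumbers.size)

    def copy(self) -> "Spectrum":
        return replace(
            self,
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities.copy(),
            accumulations=None if self.accumulations is None else self.accumulations.copy(),
            meta=dict(self.meta),
        )


@dataclass
class Cohort:
    """A patient-grouped collection of labelled spectra from one domain."""

    spectra: list[Spectrum]
    domain: str = ""

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        for s in self.spectra:
            if not s.patient_id:
                raise ValueError("every spectrum in a cohort needs a patient_id")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def patients(self) -> list[str]:
        """Distinct patient ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    @property
    def wavenumbers(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty cohort has no grid")
        return self.spectra[0].wavenumbers

    def intensity_matrix(self) -> np.ndarray:
        """Stack intensities into an ``(n_spectra, n_points)`` matrix."""
        grids = {s.n_points for s in self.spectra}
        if len(grids) > 1:
            raise ValueError(f"spectra are on different grids (lengths {sorted(grids)})")
        return np.stack([s.intensities for s in self.spectra])

    def labels(self) -> np.ndarray:
        """Labels as an int array; raises if any label is unknown."""
        if any(s.label == UNKNOWN_LABEL for s in self.spectra):
            raise ValueError("cohort contains unlabelled spectra")
        return np.array([int(s.label) for s in self.spectra])

    def patient_ids(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.spectra])

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Cohort":
        return Cohort([self.spectra[int(i)] for i in indices], domain=self.domain)

    def select_patients(self, patient_ids: Iterable[str]) -> "Cohort":
        wanted = set(patient_ids)
        return Cohort([s for s in self.spectra if s.patient_id in wanted], domain=self.domain)

    def map(self, fn) -> "Cohort":
        """Apply ``fn`` to every spectrum, returning a new cohort."""
        return Cohort([fn(s) for s in self.spectra], domain=self.domain)
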