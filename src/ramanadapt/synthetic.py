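"""Synthetic Raman cohort simulator.

Generates cohorts with the statistical structure intraoperative tissue Raman
data have: narrow vibrational peaks at literature Raman shifts riding on a
broad, smooth autofluorescence background, Gaussian detector noise, sporadic
cosmic-ray spikes affecting single accumulations, multiplicative per-patient
intensity heterogeneity, and class-dependent peak amplitudes.  Separate domain
presets emulate the source cohorts used for pre-training (an abundant
bacteria-like domain plus brain / breast / retrospective-prostate cancer
cohorts) and a small prospective prostate target domain, so that transfer
learning and test-time adaptation can be exercised end to end without any
real data.

The generator is fully deterministic given ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cohort import Cohort, Spectrum

__all__ = [
    "PeakSpec",
    "DomainSpec",
    "DEFAULT_GRID",
    "DEFAULT_PEAKS",
    "default_grid",
    "generate_cohort",
    "shift_domain",
    "render_clean_spectrum",
    "bacteria_like_domain",
    "brain_domain",
    "breast_domain",
    "prostate_retrospective_domain",
    "prostate_target_domain",
]

#: Default acquisition grid: 1174 evenly spaced points on 400-2000 cm^-1.
DEFAULT_GRID = (400.0, 2000.0, 1174)


def default_grid() -> np.ndarray:
    lo, hi, n = DEFAULT_GRID
    return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band.

    ``class_effect`` multiplies the amplitude for cancer-labelled sites;
    ``1.0`` means the band carries no class information.
    """

    center: float  # cm^-1
    width: float  # half-width at half-maximum, cm^-1
    base_amplitude: float  # a.u.
    class_effect: float = 1.0
    shape: str = "lorentzian"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"PeakSpec.width must be > 0, got {self.width}")
        if self.base_amplitude < 0:
            raise ValueError(f"PeakSpec.base_amplitude must be >= 0, got {self.base_amplitude}")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"PeakSpec.shape must be lorentzian|gaussian, got {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-amplitude line shape on the given grid."""
        x = (wavenumbers - self.center) / self.width
        if self.shape == "lorentzian":
            return 1.0 / (1.0 + x * x)
        return np.exp(-0.5 * x * x)


def _default_peaks() -> tuple[PeakSpec, ...]:
    # Literature prostate-relevant Raman shifts: tryptophan (881),
    # phenylalanine (994/997/1007, 1583, 1602 with tyrosine/tryptophan),
    # collagen/DNA/RNA (1307-1310, 1334), beta-carotene (1396),
    # DNA/RNA/proteins/phospholipids (1766, 1772).
    amps = {
        881.0: 0.55, 994.0: 0.50, 997.0: 0.70, 1007.0: 0.60, 1309.0: 0.65,
        1334.0: 0.60, 1396.0: 0.40, 1583.0: 0.45, 1602.0: 0.50,
        1766.0: 0.30, 1772.0: 0.30,
    }
    return tuple(PeakSpec(center=c, width=8.0, base_amplitude=a) for c, a in amps.items())


#: Default class-neutral peak set at the literature Raman shifts.
DEFAULT_PEAKS: tuple[PeakSpec, ...] = _default_peaks()


@dataclass(frozen=True)
class DomainSpec:
    """Statistical description of one acquisition domain."""

    name: str
    peaks: tuple[PeakSpec, ...] = DEFAULT_PEAKS
    baseline_amplitude: float = 5.0  # a.u., scale of the autofluorescence background
    baseline_smoothness: float = 350.0  # characteristic Gaussian width, cm^-1
    noise_sd: float = 0.05  # a.u., per accumulation
    cosmic_ray_rate: float = 0.05  # expected spikes per accumulation
    patient_effect_sd: float = 0.15  # SD of log per-patient intensity factor
    n_accumulations: int = 10
    class_balance: float = 0.5  # fraction of cancer sites
    grid: tuple[float, float, int] = DEFAULT_GRID

    def __post_init__(self) -> None:
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError(f"DomainSpec.class_balance must be in [0, 1], got {self.class_balance}")
        if self.noise_sd < 0:
            raise ValueError(f"DomainSpec.noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_accumulations < 1:
            raise ValueError(f"DomainSpec.n_accumulations must be >= 1, got {self.n_accumulations}")
        if self.baseline_amplitude < 0:
            raise ValueError(f"DomainSpec.baseline_amplitude must be >= 0, got {self.baseline_amplitude}")
        if self.cosmic_ray_rate < 0:
            raise ValueError(f"DomainSpec.cosmic_ray_rate must be >= 0, got {self.cosmic_ray_rate}")
        if self.patient_effect_sd < 0:
            raise ValueError(f"DomainSpec.patient_effect_sd must be >= 0, got {self.patient_effect_sd}")
        lo, hi, n = self.grid
        if n < 2 or hi <= lo:
            raise ValueError(f"DomainSpec.grid must be (lo < hi, n >= 2), got {self.grid}")
        for p in self.peaks:
            if not lo <= p.center <= hi:
                raise ValueError(
                    f"peak center {p.center} cm^-1 outside grid range [{lo}, {hi}]"
                )

    def wavenumbers(self) -> np.ndarray:
        lo, hi, n = self.grid
        return np.linspace(lo, hi, n)


def render_clean_spectrum(
    spec: DomainSpec, label: int, *, include_baseline: bool = True,
    baseline_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noise-free spectrum for one site: baseline + class-modulated peaks.

    With ``baseline_rng=None`` a deterministic 3-Gaussian baseline is used,
    which is convenient for fixtures; the cohort generator passes a seeded
    generator so baselines vary between measurements.
    """
    wn = spec.wavenumbers()
    y = np.zeros_like(wn)
    for p in spec.peaks:
        amp = p.base_amplitude * (p.class_effect if label == 1 else 1.0)
        y += amp * p.profile(wn)
    if include_baseline and spec.baseline_amplitude > 0:
        y += _autofluorescence(spec, baseline_rng)
    return y


def _autofluorescence(spec: DomainSpec, rng: np.random.Generator | None) -> np.ndarray:
    """Broad fluorescence background: a sum of 3 wide Gaussians.

    Component centres/widths/amplitudes are mildly jittered per measurement
    when an rng is given; the component widths are much larger than any
    Raman line so the background carries no narrow features.
    """
    wn = spec.wavenumbers()
    lo, hi, _ = spec.grid
    span = hi - lo
    centers = np.array([lo + 0.15 * span, lo + 0.5 * span, lo + 0.85 * span])
    widths = np.full(3, spec.baseline_smoothness)
    amps = spec.baseline_amplitude * np.array([0.9, 1.0, 0.55])
    if rng is not None:
        centers = centers + rng.normal(0.0, 0.03 * span, size=3)
        widths = widths * rng.uniform(0.85, 1.15, size=3)
        amps = amps * rng.uniform(0.8, 1.2, size=3)
    y = np.zeros_like(wn)
    for c, w, a in zip(centers, widths, amps):
        y += a * np.exp(-0.5 * ((wn - c) / w) ** 2)
    return y


def _add_cosmic_rays(acc: np.ndarray, spec: DomainSpec, rng: np.random.Generator) -> None:
    """Poisson-placed narrow spikes, 20-100x the noise SD, width 1-2 points."""
    n_acc, n_pts = acc.shape
    scale = max(spec.noise_sd, 1e-12)
    for i in range(n_acc):
        for _ in range(rng.poisson(spec.cosmic_ray_rate)):
            pos = int(rng.integers(0, n_pts))
            amp = rng.uniform(20.0, 100.0) * scale
            acc[i, pos] += amp
            if rng.random() < 0.5 and pos + 1 < n_pts:  # occasional 2-point spike
                acc[i, pos + 1] += 0.6 * amp


def generate_cohort(
    spec: DomainSpec,
    n_patients: int,
    spectra_per_patient: int | tuple[int, int],
    seed: int,
) -> Cohort:
    """Simulate a patient-grouped cohort of raw spectra.

    Each site's raw accumulation matrix is
    ``patient_factor * (baseline + class-modulated peaks) + noise + spikes``;
    ``Spectrum.intensities`` holds the plain accumulation average (the
    preprocessing chain is expected to redo this properly after cosmic-ray
    removal).  Labels are drawn per measurement site, reflecting site-specific
    ground truth rather than a per-patient diagnosis.

    Identical ``(spec, n_patients, spectra_per_patient, seed)`` give a
    bit-identical cohort.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if isinstance(spectra_per_patient, int):
        lo_n, hi_n = spectra_per_patient, spectra_per_patient
    else:
        lo_n, hi_n = spectra_per_patient
    if not 1 <= lo_n <= hi_n:
        raise ValueError(f"invalid spectra_per_patient range ({lo_n}, {hi_n})")

    rng = np.random.default_rng(seed)
    wn = spec.wavenumbers()
    # Measurements per patient follow a right-skewed count distribution
    # truncated to [lo, hi], as clinical per-patient measurement counts do
    # (most patients near the low end, a long tail upward): a Poisson with
    # mean in the lower quarter of the range, clipped to the bounds.
    lam = lo_n + (hi_n - lo_n) / 4.0
    spectra: list[Spectrum] = []
    for ip in range(n_patients):
        pid = f"{spec.name}_P{ip + 1:03d}"
        patient_factor = float(np.exp(rng.normal(0.0, spec.patient_effect_sd)))
        n_spec = int(np.clip(rng.poisson(lam), lo_n, hi_n))
        for js in range(n_spec):
            label = int(rng.random() < spec.class_balance)
            clean = render_clean_spectrum(spec, label, baseline_rng=rng)
            acc = patient_factor * clean + rng.normal(
                0.0, spec.noise_sd, size=(spec.n_accumulations, wn.size)
            )
            _add_cosmic_rays(acc, spec, rng)
            spectra.append(
                Spectrum(
                    wavenumbers=wn,
                    intensities=acc.mean(axis=0),
                    patient_id=pid,
                    sample_id=f"{pid}_S{js + 1:03d}",
                    label=label,
                    domain=spec.name,
                    accumulations=acc,
                    meta={"patient_factor": patient_factor},
                )
            )
    return Cohort(spectra, domain=spec.name)


def shift_domain(
    spec: DomainSpec,
    baseline_scale: float = 1.0,
    peak_shift: float = 0.0,
    snr_scale: float = 1.0,
) -> DomainSpec:
    """Derive a covariate-shifted variant of a domain.

    ``baseline_scale`` multiplies the autofluorescence amplitude,
    ``peak_shift`` translates every peak centre (cm^-1) and ``snr_scale``
    rescales the signal-to-noise ratio (values < 1 mean noisier data:
    ``noise_sd`` is divided by ``snr_scale``).  The input spec is unchanged.
    """
    if baseline_scale <= 0 or snr_scale <= 0:
        raise ValueError("baseline_scale and snr_scale must be > 0")
    lo, hi, _ = spec.grid
    new_peaks = []
    for p in spec.peaks:
        c = p.center + peak_shift
        if not lo <= c <= hi:
            raise ValueError(
                f"peak at {p.center} cm^-1 shifted to {c} cm^-1, outside [{lo}, {hi}]"
            )
        new_peaks.append(replace(p, center=c))
    return replace(
        spec,
        peaks=tuple(new_peaks),
        baseline_amplitude=spec.baseline_amplitude * baseline_scale,
        noise_sd=spec.noise_sd / snr_scale,
    )


def _with_class_effects(
    peaks: Sequence[PeakSpec], effects: dict[float, float]
) -> tuple[PeakSpec, ...]:
    return tuple(
        replace(p, class_effect=effects.get(p.center, p.class_effect)) for p in peaks
    )


#: Class effects shared by the tissue domains: cancer raises nucleic-acid /
#: protein bands and depresses the collagen band, a pattern consistent with
#: higher cellularity in tumour tissue.
_TISSUE_CLASS_EFFECTS = {
    997.0: 1.6, 1007.0: 1.35, 1334.0: 1.45, 1583.0: 1.3, 1309.0: 0.75,
}


def bacteria_like_domain() -> DomainSpec:
    """Abundant, high-SNR, low-fluorescence domain for first-stage pre-training."""
    return DomainSpec(
        name="bacteria_like",
        peaks=_with_class_effects(DEFAULT_PEAKS, _TISSUE_CLASS_EFFECTS),
        baseline_amplitude=1.0,
        noise_sd=0.03,
        cosmic_ray_rate=0.02,
        patient_effect_sd=0.10,
        n_accumulations=3,
        class_balance=0.5,
    )


def brain_domain() -> DomainSpec:
    """High-quality tissue domain, moderate fluorescence, cancer-rich labels."""
    return DomainSpec(
        name="brain",
        peaks=_with_class_effects(DEFAULT_PEAKS, _TISSUE_CLASS_EFFECTS),
        baseline_amplitude=2.0,
        noise_sd=0.04,
        cosmic_ray_rate=0.05,
        patient_effect_sd=0.15,
        n_accumulations=20,
        class_balance=0.574,
    )


def breast_domain() -> DomainSpec:
    return DomainSpec(
        name="breast",
        peaks=_with_class_effects(DEFAULT_PEAKS, _TISSUE_CLASS_EFFECTS),
        baseline_amplitude=2.5,
        noise_sd=0.05,
        cosmic_ray_rate=0.05,
        patient_effect_sd=0.15,
        n_accumulations=10,
        class_balance=0.651,
    )


def prostate_retrospective_domain() -> DomainSpec:
    """Retrospective prostate: strong fluorescence, heavily normal-dominated."""
    return DomainSpec(
        name="prostate_retro",
        peaks=_with_class_effects(DEFAULT_PEAKS, _TISSUE_CLASS_EFFECTS),
        baseline_amplitude=5.0,
        noise_sd=0.08,
        cosmic_ray_rate=0.05,
        patient_effect_sd=0.20,
        n_accumulations=35,
        class_balance=0.124,
    )


def prostate_target_domain() -> DomainSpec:
    """Prospective prostate target: strong fluorescence, 10 accumulations,
    cancer fraction 59/104."""
    return DomainSpec(
        name="prostate_target",
        peaks=_with_class_effects(DEFAULT_PEAKS, _TISSUE_CLASS_EFFECTS),
        baseline_amplitude=5.0,
        noise_sd=0.08,
        cosmic_ray_rate=0.05,
        patient_effect_sd=0.20,
        n_accumulations=10,
        class_balance=0.567,
    )
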