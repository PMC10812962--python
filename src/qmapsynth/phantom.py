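"""Synthetic knee phantoms for map-synthesis experiments.

A phantom subject is a stylized sagittal knee: a circular "femur" of bone
surrounded by an annular cartilage shell, embedded in muscle within an
elliptical body outline.  The shell is divided by angular sectors into the
six cartilage compartments used in compartmental knee analysis — medial and
lateral femoral condyle (MF, LF), medial and lateral tibial (MT, LT),
patellar (PAT) and trochlear (TRO) cartilage.  The geometry is deliberately
schematic: downstream code needs contiguous labelled compartments and
realistic relaxation-time statistics, not anatomy.

Relaxation-time fields are built T2-first: each compartment draws a
subject-level baseline, modulated by a smooth spatial field plus per-voxel
jitter.  T1rho is then a fixed compartment-wise affine function of T2
(slope = spread ratio), so that across subjects T1rho is a deterministic,
learnable function of (T2, compartment) — mirroring the empirical coupling
between the two relaxation times in cartilage.  Focal OA-like lesions break
this coupling: they elevate T1rho by a configurable fraction and T2 by half
that fraction, encoding that T1rho carries information beyond T2.

Echo series follow the mono-exponential decay S(t) = S0*exp(-t/T) at the
preparation times of the acquisition, with additive Gaussian noise.
Domain-shift corruption (smooth multiplicative coil-bias field, SNR
rescaling, global relaxation-time offset) emulates a change of coil or
scanner.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .relaxometry import EchoSeries, MapKind, QuantMap

logger = logging.getLogger("qmapsynth.phantom")

#: The six cartilage compartments, in canonical order.
CARTILAGE_COMPARTMENTS: Tuple[str, ...] = ("MF", "LF", "MT", "LT", "PAT", "TRO")

#: Label codes: 0 background, 1-6 cartilage compartments, then bone, muscle.
LABEL_TABLE: Dict[str, int] = {
    "background": 0,
    "MF": 1,
    "LF": 2,
    "MT": 3,
    "LT": 4,
    "PAT": 5,
    "TRO": 6,
    "bone": 7,
    "muscle": 8,
}


def _subject_seed(seed: int, subject_id: str, salt: str = "") -> int:
    """Stable per-subject substream seed (< 2**31)."""
    h = zlib.crc32((subject_id + "|" + salt).encode())
    return int((seed * 2654435761 + h) % (2**31 - 1))


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSpec:
    """Preparation-time schedules of the mapping acquisition.

    The default four-point schedules (TSL 0/10/40/80 ms; TE 0/12.9/25.7/51.4
    ms) are the ones shared by all acquisition protocols this package
    targets.  Everything in ``metadata`` (spin-lock frequency, TR, matrix,
    acceleration...) is informational only and never enters a computation.
    """

    tsl_times_ms: Tuple[float, ...] = (0.0, 10.0, 40.0, 80.0)
    te_times_ms: Tuple[float, ...] = (0.0, 12.9, 25.7, 51.4)
    metadata: Dict[str, object] = field(
        default_factory=lambda: {
            "spin_lock_frequency_hz": 500.0,
            "field_strength_T": 3.0,
            "tr_s": 1.2,
            "slice_thickness_mm": 4.0,
        }
    )

    def __post_init__(self) -> None:
        for name, times in (("tsl", self.tsl_times_ms), ("te", self.te_times_ms)):
            t = np.asarray(times, float)
            if t.size < 2:
                raise ValueError(f"{name} schedule needs at least two times")
            if t[0] < 0 or np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} times must be non-negative and strictly increasing")

    def times_for(self, kind: MapKind) -> np.ndarray:
        return np.asarray(self.tsl_times_ms if kind == "T1rho" else self.te_times_ms, float)


@dataclass(frozen=True)
class TissueParams:
    """Mean and spread (SD across subjects) of one tissue class."""

    t1rho_ms: float
    t1rho_spread_ms: float
    t2_ms: float
    t2_spread_ms: float
    s0: float
    s0_spread: float

    def __post_init__(self) -> None:
        if min(self.t1rho_ms, self.t2_ms, self.s0) <= 0 and self.s0 != 0.0:
            raise ValueError("tissue relaxation times and S0 must be positive")


def default_tissue_params() -> Dict[str, TissueParams]:
    """Tissue statistics loosely matching healthy-to-early-OA knee values:
    cartilage T1rho in the low-40s ms, T2 markedly shorter, with T1rho
    spread exceeding T2 spread."""
    return {
        "cartilage": TissueParams(43.0, 3.0, 33.0, 2.5, 100.0, 5.0),
        "bone": TissueParams(25.0, 2.0, 20.0, 1.5, 30.0, 3.0),
        "muscle": TissueParams(38.0, 2.0, 30.0, 1.5, 80.0, 4.0),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a cohort of phantom subjects.

    ``noise_sigma`` is the additive echo-noise SD as a fraction of the mean
    cartilage S0.  ``lesion_rate`` is the expected number of focal T1rho
    elevations per subject (Poisson); each lesion elevates T1rho by
    ``lesion_magnitude`` (fractional) and T2 by ``lesion_magnitude *
    lesion_t2_ratio``.
    """

    matrix_size: Tuple[int, int, int] = (8, 64, 64)  # (slices, rows, cols)
    n_subjects: int = 30
    tissue_params: Dict[str, TissueParams] = field(default_factory=default_tissue_params)
    lesion_rate: float = 1.5
    lesion_magnitude: float = 0.25
    lesion_t2_ratio: float = 0.5
    #: systematic per-compartment T1rho mean offsets (MF, LF, MT, LT, PAT,
    #: TRO), zero-sum so the cartilage-wide mean is preserved; they make the
    #: T2 -> T1rho law compartment-dependent, which no global rescaling of
    #: T2 can reproduce.
    compartment_t1rho_offset_ms: Tuple[float, ...] = (3.0, -1.5, -3.0, 1.5, -2.5, 2.5)
    noise_sigma: float = 0.01
    smooth_amplitude: float = 0.04
    smooth_scale_vox: float = 6.0
    jitter_sd_ms: float = 0.5
    rician_noise: bool = False
    seed: int = 2024

    def __post_init__(self) -> None:
        s, r, c = self.matrix_size
        if s < 1 or min(r, c) < 32:
            raise ValueError(
                "matrix too small to place six cartilage compartments: need "
                f">=1 slice and in-plane size >=32, got {self.matrix_size}"
            )
        cart = self.tissue_params["cartilage"]
        if cart.t1rho_ms <= cart.t2_ms:
            raise ValueError("cartilage T1rho mean must exceed cartilage T2 mean")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.lesion_rate < 0 or self.lesion_magnitude < 0:
            raise ValueError("lesion parameters must be >= 0")
        if len(self.compartment_t1rho_offset_ms) != len(CARTILAGE_COMPARTMENTS):
            raise ValueError("need one T1rho offset per cartilage compartment")


@dataclass(frozen=True)
class DomainShiftSpec:
    """Coil/scanner-change corruption applied to an echo series.

    bias_field_amplitude : fractional amplitude (SD) of one smooth
        multiplicative sensitivity field shared by all echoes.
    snr_scale : multiplier on the additive noise SD (2.0 = SNR halved).
    global_offset_ms : additive shift of the underlying relaxation times,
        emulating systematic coil/scanner-dependent map differences.
    """

    bias_field_amplitude: float = 0.10
    bias_field_scale: float = 12.0
    snr_scale: float = 2.0
    global_offset_ms: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.bias_field_amplitude < 0:
            raise ValueError("bias_field_amplitude must be >= 0")
        if self.snr_scale <= 0:
            raise ValueError("snr_scale must be > 0")


# ---------------------------------------------------------------------------
# labelled geometry + truth containers
# ---------------------------------------------------------------------------

@dataclass
class CompartmentLabels:
    """Integer label volume with its code table."""

    label_volume: np.ndarray
    label_table: Dict[str, int] = field(default_factory=lambda: dict(LABEL_TABLE))

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label volume must be 3D")

    def mask(self, name: str) -> np.ndarray:
        if name not in self.label_table:
            raise KeyError(f"unknown label {name!r}")
        return self.label_volume == self.label_table[name]

    @property
    def cartilage_mask(self) -> np.ndarray:
        m = np.zeros(self.label_volume.shape, dtype=bool)
        for name in CARTILAGE_COMPARTMENTS:
            m |= self.mask(name)
        return m


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject."""

    t1rho_truth: QuantMap
    t2_truth: QuantMap
    s0: np.ndarray
    labels: CompartmentLabels
    subject_id: str
    spec_used: PhantomSpec

    def __post_init__(self) -> None:
        shapes = {
            self.t1rho_truth.shape,
            self.t2_truth.shape,
            self.s0.shape,
            self.labels.label_volume.shape,
        }
        if len(shapes) != 1:
            raise ValueError("truth volumes must share one geometry")


def make_labels(matrix_size: Tuple[int, int, int]) -> CompartmentLabels:
    """Build the stylized label geometry for one subject.

    Per slice: a bone disc, a cartilage annulus split into six equal angular
    sectors (one per compartment), muscle inside an elliptical body outline,
    background outside.  The disc radius tapers towards the end slices to
    give the volume 3D structure.
    """
    ns, nr, nc = matrix_size
    lab = np.zeros(matrix_size, dtype=np.int16)
    rr, cc = np.mgrid[0:nr, 0:nc]
    cy, cx = 0.45 * nr, 0.5 * nc
    base_r = 0.26 * min(nr, nc)
    shell = max(2.0, 0.08 * min(nr, nc))
    body = ((rr - nr / 2) / (0.48 * nr)) ** 2 + ((cc - nc / 2) / (0.48 * nc)) ** 2 <= 1.0

    # angular sector -> compartment, six equal 60-degree sectors
    theta = np.arctan2(rr - cy, cc - cx)  # (-pi, pi]
    sector = np.floor((theta + np.pi) / (2 * np.pi / 6)).astype(int)
    sector = np.clip(sector, 0, 5)
    sector_code = np.array(
        [LABEL_TABLE[n] for n in ("MT", "LT", "MF", "PAT", "TRO", "LF")], dtype=np.int16
    )

    for s in range(ns):
        taper = 1.0 - 0.3 * abs(2 * s - (ns - 1)) / max(ns - 1, 1)
        r_bone = base_r * taper
        dist = np.hypot(rr - cy, cc - cx)
        sl = np.zeros((nr, nc), dtype=np.int16)
        sl[body] = LABEL_TABLE["muscle"]
        ann = (dist > r_bone) & (dist <= r_bone + shell) & body
        sl[ann] = sector_code[sector[ann]]
        sl[dist <= r_bone] = LABEL_TABLE["bone"]
        lab[s] = sl

    labels = CompartmentLabels(lab)
    for name in CARTILAGE_COMPARTMENTS:
        if not labels.mask(name).any():
            raise ValueError(f"matrix too small: compartment {name} is empty")
    return labels


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, scale_vox: float) -> np.ndarray:
    """Unit-SD smooth random field (Gaussian-filtered white noise)."""
    g = gaussian_filter(rng.standard_normal(shape), sigma=(1.0, scale_vox, scale_vox))
    sd = g.std()
    return g / sd if sd > 0 else g


def generate_phantom(spec: PhantomSpec, subject_id: str) -> PhantomTruth:
    """Generate one phantom subject, deterministic in (spec.seed, subject_id).

    T2 is generated first (compartment baseline + smooth field + jitter);
    T1rho follows as a fixed affine function of T2 within each tissue class,
    slope = t1rho_spread / t2_spread, plus a systematic per-compartment
    offset, so subject-to-subject variation in T2 propagates to T1rho and
    the mapping is learnable across subjects — but only with knowledge of
    the compartment, not from the T2 value alone.  Lesions then elevate
    T1rho by ``lesion_magnitude`` and T2 by ``lesion_magnitude *
    lesion_t2_ratio`` fractions of the tissue means.
    """
    rng = np.random.default_rng(_subject_seed(spec.seed, subject_id, "truth"))
    labels = make_labels(spec.matrix_size)
    lab = labels.label_volume

    t2 = np.zeros(spec.matrix_size, dtype=float)
    t1r = np.zeros(spec.matrix_size, dtype=float)
    s0 = np.zeros(spec.matrix_size, dtype=float)

    smooth = _smooth_field(rng, spec.matrix_size, spec.smooth_scale_vox)
    jitter = rng.standard_normal(spec.matrix_size) * spec.jitter_sd_ms

    tissue_of = {name: "cartilage" for name in CARTILAGE_COMPARTMENTS}
    tissue_of.update({"bone": "bone", "muscle": "muscle"})

    for name, tissue in tissue_of.items():
        p = spec.tissue_params[tissue]
        m = labels.mask(name)
        if not m.any():
            continue
        t2_base = rng.normal(p.t2_ms, p.t2_spread_ms)
        s0_base = rng.normal(p.s0, p.s0_spread)
        t2_vox = t2_base + p.t2_ms * spec.smooth_amplitude * smooth[m] + jitter[m]
        slope = p.t1rho_spread_ms / p.t2_spread_ms
        offset = 0.0
        if name in CARTILAGE_COMPARTMENTS:
            offset = spec.compartment_t1rho_offset_ms[CARTILAGE_COMPARTMENTS.index(name)]
        t2[m] = t2_vox
        t1r[m] = p.t1rho_ms + offset + slope * (t2_vox - p.t2_ms)
        s0[m] = s0_base

    # focal OA-like lesions: localized patches of elevated relaxation times
    n_lesions = rng.poisson(spec.lesion_rate)
    cart_p = spec.tissue_params["cartilage"]
    for _ in range(n_lesions):
        comp = CARTILAGE_COMPARTMENTS[rng.integers(len(CARTILAGE_COMPARTMENTS))]
        m = labels.mask(comp)
        vox = np.argwhere(m)
        zc, yc, xc = vox[rng.integers(len(vox))]
        zz, yy, xx = np.mgrid[0 : lab.shape[0], 0 : lab.shape[1], 0 : lab.shape[2]]
        blob = np.exp(
            -(
                ((zz - zc) / 1.0) ** 2
                + ((yy - yc) / 3.0) ** 2
                + ((xx - xc) / 3.0) ** 2
            )
            / 2.0
        )
        blob = np.where(m, blob, 0.0)  # lesion confined to its compartment
        t1r += spec.lesion_magnitude * cart_p.t1rho_ms * blob
        t2 += spec.lesion_magnitude * spec.lesion_t2_ratio * cart_p.t2_ms * blob

    t2 = np.maximum(t2, 0.0)
    t1r = np.maximum(t1r, 0.0)
    inside = lab != LABEL_TABLE["background"]
    t2[inside] = np.maximum(t2[inside], 1.0)
    t1r[inside] = np.maximum(t1r[inside], 1.0)

    return PhantomTruth(
        t1rho_truth=QuantMap(t1r, "T1rho"),
        t2_truth=QuantMap(t2, "T2"),
        s0=s0,
        labels=labels,
        subject_id=subject_id,
        spec_used=spec,
    )


# ---------------------------------------------------------------------------
# echo simulation and domain shift
# ---------------------------------------------------------------------------

def simulate_echoes(
    truth: PhantomTruth,
    acq: AcquisitionSpec,
    kind: MapKind,
    noise_sigma: Optional[float] = None,
    seed: int = 0,
    rician: Optional[bool] = None,
) -> EchoSeries:
    """Simulate the weighted-image stack for one preparation kind.

    Noiseless signal at echo time t is S0*exp(-t/T); additive Gaussian noise
    (or Rician magnitude noise if requested) with SD = noise_sigma * mean
    cartilage S0 is added on top.  Echoes are registered by construction.
    """
    if kind not in ("T1rho", "T2"):
        raise ValueError(f"unknown series kind {kind!r}")
    spec = truth.spec_used
    if noise_sigma is None:
        noise_sigma = spec.noise_sigma
    if rician is None:
        rician = spec.rician_noise
    t = acq.times_for(kind)
    T = (truth.t1rho_truth if kind == "T1rho" else truth.t2_truth).values_ms
    S0 = truth.s0

    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-t[:, None, None, None] / T[None])
    decay = np.where(T[None] > 0, decay, 0.0)
    decay[0] = np.where(T > 0, decay[0], 1.0)  # t=0 echo equals S0 regardless
    data = S0[None] * decay

    cart = truth.labels.cartilage_mask
    sigma_au = float(noise_sigma) * float(S0[cart].mean()) if cart.any() else 0.0
    if sigma_au > 0:
        rng = np.random.default_rng(_subject_seed(seed, truth.subject_id, "echo" + kind))
        if rician:
            re = data + rng.normal(0.0, sigma_au, data.shape)
            im = rng.normal(0.0, sigma_au, data.shape)
            data = np.hypot(re, im)
        else:
            data = data + rng.normal(0.0, sigma_au, data.shape)
    return EchoSeries(data=data, times_ms=t, kind=kind, noise_sigma_au=sigma_au)


def apply_domain_shift(
    series: EchoSeries,
    shift: DomainShiftSpec,
    truth_map: Optional[QuantMap] = None,
) -> EchoSeries:
    """Corrupt an echo series as a coil/scanner change would.

    One smooth positive multiplicative bias field is shared by every echo
    (coil sensitivity is static), additive noise is rescaled to
    ``snr_scale`` times the series' nominal level, and a non-zero
    ``global_offset_ms`` re-exponentiates the decay to T + offset (this
    needs ``truth_map`` of the matching kind).  Deterministic under
    ``shift.seed``.
    """
    data = series.data.astype(float).copy()
    t = series.times_ms
    rng = np.random.default_rng(int(shift.seed) % (2**31 - 1))

    if shift.global_offset_ms != 0.0:
        if truth_map is None:
            raise ValueError("global_offset_ms requires the matching truth map")
        if truth_map.kind != series.kind:
            raise ValueError("truth map kind does not match series kind")
        T = truth_map.values_ms
        Ts = T + shift.global_offset_ms
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.exp(t[:, None, None, None] * (1.0 / T[None] - 1.0 / Ts[None]))
        ratio = np.where((T[None] > 0) & (Ts[None] > 0), ratio, 1.0)
        data = data * ratio

    if shift.bias_field_amplitude > 0:
        g = gaussian_filter(
            rng.standard_normal(series.shape),
            sigma=(1.0, shift.bias_field_scale, shift.bias_field_scale),
        )
        g = g / g.std() if g.std() > 0 else g
        bias = np.maximum(1.0 + shift.bias_field_amplitude * g, 0.05)
        data = data * bias[None]

    sigma_new = series.noise_sigma_au * shift.snr_scale
    if shift.snr_scale != 1.0 and series.noise_sigma_au > 0:
        if shift.snr_scale < 1.0:
            raise ValueError("cannot reduce noise already present (snr_scale < 1)")
        extra = np.sqrt(sigma_new**2 - series.noise_sigma_au**2)
        data = data + rng.normal(0.0, extra, data.shape)

    return EchoSeries(
        data=data,
        times_ms=t,
        kind=series.kind,
        spacing=series.spacing,
        noise_sigma_au=sigma_new,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSubject:
    truth: PhantomTruth
    echoes_t1rho: EchoSeries
    echoes_t2: EchoSeries


def make_cohort(
    spec: PhantomSpec,
    acq: Optional[AcquisitionSpec] = None,
    subject_ids: Optional[Sequence[str]] = None,
) -> List[CohortSubject]:
    """Generate ``spec.n_subjects`` phantom subjects with echo series.

    Subject ids default to S001..S{n}; duplicates are rejected.  All
    randomness derives from ``spec.seed`` and the subject id, so the same
    spec regenerates a voxel-identical cohort.
    """
    acq = acq or AcquisitionSpec()
    if subject_ids is None:
        subject_ids = [f"S{i + 1:03d}" for i in range(spec.n_subjects)]
    subject_ids = list(subject_ids)
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids in cohort")
    if len(subject_ids) != spec.n_subjects:
        raise ValueError("subject id list length != spec.n_subjects")

    cohort = []
    for sid in subject_ids:
        truth = generate_phantom(spec, sid)
        cohort.append(
            CohortSubject(
                truth=truth,
                echoes_t1rho=simulate_echoes(truth, acq, "T1rho", seed=spec.seed),
                echoes_t2=simulate_echoes(truth, acq, "T2", seed=spec.seed),
            )
        )
    logger.info("generated cohort of %d subjects at %s", len(cohort), spec.matrix_size)
    return cohort
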