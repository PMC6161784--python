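"""Synthetic PET cohort generator.

Emulates the study population the analysis was designed for: ~70 metastatic
castration-resistant prostate-cancer patients imaged with a PSMA tracer on a
~5 mm grid, each with three bone lesions, lymph-node lesions in roughly 47%
of patients and liver/prostate ("other") lesions in roughly 21%, lesion
volumes between 7.8 and 82.3 cm^3, and a ~60/40 responder/non-responder
split on the PSA delta.

Each patient carries a latent heterogeneity score ``h`` on a standard-normal
scale. Lesion texture is a Gaussian random field -- smoothed white noise
plus a fine white-noise component whose weight grows with ``h`` -- so the
field's spatial correlation length decreases monotonically with ``h``:
higher ``h`` means finer texture, hence higher GLCM entropy and lower
homogeneity. The field is rank-rescaled onto the lesion's SUV band (uniform
gray-level occupancy), which keeps the quantized texture features a clean
monotone readout of the correlation length. The PSA delta is tied to ``h`` through a
Gaussian copula calibrated on the Spearman scale: a target rank correlation
``rho_s`` maps to the copula's Pearson parameter via ``r = 2 sin(pi rho_s / 6)``,
and the delta's marginal is a sign-split lognormal with P(delta < 0) equal
to the responder-fraction target. AP and bAP deltas get their own, weaker
links. Lesion volume is drawn independently of ``h``.

All randomness flows from the single integer seed in :class:`PhantomSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from scipy.ndimage import gaussian_filter

from .imgio import PETVolume, VOIMask

__all__ = [
    "PhantomSpec",
    "CohortBundle",
    "LesionRecord",
    "generate_lesion_image",
    "generate_cohort",
    "generate_fast_cohort",
    "rng_for_replicate",
    "spearman_to_pearson",
    "CLINICAL_COLUMNS",
]

CLINICAL_COLUMNS = [
    "patient_id", "site", "lesion_id",
    "pre_psa", "post_psa", "pre_ap", "post_ap", "pre_bap", "post_bap",
    "ecog_pre", "ecog_post",
]

# latent-h clamp: at or below H_MIN the lesion degenerates to a constant field
H_MIN = -4.0
# texture field: coarse component (white noise smoothed with this kernel, in
# voxels) mixed with a fine white component whose weight grows with h; the
# mixture's correlation length decreases monotonically with h
COARSE_SIGMA = 2.0
FINE_WEIGHT_SCALE, FINE_WEIGHT_RATE = 0.3, 0.45

# marginal magnitudes (lognormal) for the clinical markers, chosen as
# realistic mCRPC scales; see docs/methods.md
_MARKER_MAGNITUDE = {  # marker -> (log-mu of |delta|, log-sigma)
    "psa": (math.log(30.0), 1.0),
    "ap": (math.log(40.0), 0.8),
    "bap": (math.log(15.0), 0.8),
}
_PRE_MARGINAL = {  # marker -> (log-mu of pre value, log-sigma)
    "psa": (math.log(100.0), 1.2),
    "ap": (math.log(150.0), 0.5),
    "bap": (math.log(40.0), 0.6),
}


def _fine_weight(h: float) -> float:
    """Weight of the fine-noise component; strictly increasing in h."""
    return FINE_WEIGHT_SCALE * math.exp(FINE_WEIGHT_RATE * h)


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson parameter giving Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def rng_for_replicate(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator derived from one base seed."""
    return np.random.default_rng([int(seed), int(replicate)])


@dataclass
class PhantomSpec:
    """All knobs of the synthetic cohort; defaults mirror the study design."""

    n_patients: int = 70
    voxel_spacing_mm: tuple[float, float, float] = (5.3, 5.3, 5.0)
    n_bone: int = 3
    n_lymph_node: int = 3
    p_lymph_node: float = 33 / 70
    p_other: float = 15 / 70
    max_other: int = 3
    lesion_volume_range_cm3: tuple[float, float] = (7.8, 82.3)
    heterogeneity_link_rho: float = -0.33
    ap_link_rho: float = -0.20
    bap_link_rho: float = -0.15
    responder_fraction_target: float = 0.60
    ap_responder_fraction: float = 41 / 70
    bap_responder_fraction: float = 39 / 70
    background_suv: float = 1.0
    lesion_suv_mean_range: tuple[float, float] = (5.0, 15.0)
    lesion_contrast_fraction: float = 0.6
    noise_sd: float = 0.1
    min_voxel_floor: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        self.lesion_volume_range_cm3 = tuple(float(v) for v in self.lesion_volume_range_cm3)
        self.lesion_suv_mean_range = tuple(float(v) for v in self.lesion_suv_mean_range)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if any(s <= 0 for s in self.voxel_spacing_mm) or len(self.voxel_spacing_mm) != 3:
            raise ValueError(f"voxel spacing must be 3 positive values: {self.voxel_spacing_mm}")
        for name in ("lesion_volume_range_cm3", "lesion_suv_mean_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy low < high, got ({lo}, {hi})")
        for name in ("heterogeneity_link_rho", "ap_link_rho", "bap_link_rho"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"|{name}| must be <= 1, got {getattr(self, name)}")
        for name in ("responder_fraction_target", "ap_responder_fraction", "bap_responder_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {getattr(self, name)}")
        if not 0 <= self.p_lymph_node <= 1 or not 0 <= self.p_other <= 1:
            raise ValueError("site probabilities must lie in [0, 1]")
        if self.n_bone < 1:
            raise ValueError("every patient must have at least one bone lesion")
        if not 0 < self.lesion_contrast_fraction < 1:
            raise ValueError("lesion_contrast_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_voxel_floor < 2:
            raise ValueError("min_voxel_floor must be >= 2")

    @property
    def voxel_volume_cm3(self) -> float:
        return math.prod(self.voxel_spacing_mm) / 1000.0

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("phantom", data))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel_spacing_mm"] = list(self.voxel_spacing_mm)
        d["lesion_volume_range_cm3"] = list(self.lesion_volume_range_cm3)
        d["lesion_suv_mean_range"] = list(self.lesion_suv_mean_range)
        return d


@dataclass
class LesionRecord:
    patient_id: str
    site: str
    lesion_id: str
    requested_volume_cm3: float
    volume: PETVolume
    mask: VOIMask
    h: float


@dataclass
class CohortBundle:
    """One synthetic cohort: lesion images, clinical table, latent truth."""

    lesions: list
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame
    spec: PhantomSpec

    def write(self, outdir) -> Path:
        """Write NIfTI volumes/masks plus clinical, manifest and truth CSVs."""
        from .imgio import write_mask, write_volume

        outdir = Path(outdir)
        (outdir / "volumes").mkdir(parents=True, exist_ok=True)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
        manifest = []
        for rec in self.lesions:
            stem = f"{rec.patient_id}_{rec.site}_{rec.lesion_id}"
            vol_path = outdir / "volumes" / f"{stem}.nii.gz"
            mask_path = outdir / "masks" / f"{stem}_mask.nii.gz"
            write_volume(rec.volume, vol_path)
            write_mask(rec.mask, mask_path, spacing_mm=rec.volume.spacing_mm)
            manifest.append(
                {
                    "patient_id": rec.patient_id,
                    "site": rec.site,
                    "lesion_id": rec.lesion_id,
                    "volume_file": str(vol_path.relative_to(outdir)),
                    "mask_file": str(mask_path.relative_to(outdir)),
                }
            )
        pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
        self.clinical.to_csv(outdir / "clinical.csv", index=False)
        self.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        return outdir


def _delta_from_uniform(u: np.ndarray, responder_fraction: float, log_mu: float, log_sigma: float) -> np.ndarray:
    """Monotone quantile transform: copula uniform -> signed marker delta.

    Negative branch (probability mass = responder fraction) and positive
    branch both carry lognormal magnitudes, so the delta is heavy-tailed and
    strictly increasing in u with P(delta < 0) = responder_fraction.
    """
    u = np.asarray(u, dtype=np.float64)
    q = responder_fraction
    out = np.empty_like(u)
    neg = u < q
    un = np.clip(u[neg] / q, 1e-12, 1 - 1e-12)
    out[neg] = -np.exp(log_mu + log_sigma * sps.norm.ppf(1.0 - un))
    up = np.clip((u[~neg] - q) / (1.0 - q), 1e-12, 1 - 1e-12)
    out[~neg] = np.exp(log_mu + log_sigma * sps.norm.ppf(up))
    return out


def _linked_deltas(h: np.ndarray, rho_s: float, responder_fraction: float,
                   marker: str, rng: np.random.Generator) -> np.ndarray:
    """Draw marker deltas rank-correlated with h at Spearman strength rho_s."""
    r = spearman_to_pearson(rho_s)
    z = r * h + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(h.size)
    u = sps.norm.cdf(z)
    log_mu, log_sigma = _MARKER_MAGNITUDE[marker]
    return _delta_from_uniform(u, responder_fraction, log_mu, log_sigma)


def _pre_values(delta: np.ndarray, marker: str, rng: np.random.Generator) -> np.ndarray:
    """Positive pre-therapy values; bumped up where needed so post stays > 0."""
    log_mu, log_sigma = _PRE_MARGINAL[marker]
    pre = np.exp(log_mu + log_sigma * rng.standard_normal(delta.size))
    need = pre + delta <= 0
    pre[need] = 1.1 * np.abs(delta[need])
    return pre


def generate_lesion_image(
    volume_cm3: float,
    heterogeneity_h: float,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    patient_id: str = "P000",
    site: str = "bone",
    lesion_id: str = "L0",
) -> tuple[PETVolume, VOIMask]:
    """Synthesize one lesion: ellipsoidal mask + tunable-heterogeneity field.

    The mask holds ``round(volume / voxel volume)`` voxels (so the realized
    volume is within one voxel-volume of the request), selected as the
    voxels closest to the lesion's ellipsoidal center. Voxel values inside
    the mask come from a Gaussian random field -- a smooth component plus a
    fine white component whose weight grows with ``heterogeneity_h``, so the
    field's correlation length shrinks monotonically as ``h`` rises --
    rank-rescaled onto the lesion SUV band; at ``h <= -4`` the field
    degenerates to a constant. Background is uniform at
    ``spec.background_suv``; optional white noise is added last.

    Two calls with the same fresh ``rng`` (or with ``rng=None`` and the same
    ``spec.seed``) are bit-identical.
    """
    lo, hi = spec.lesion_volume_range_cm3
    if not lo <= volume_cm3 <= hi:
        raise ValueError(
            f"volume {volume_cm3} cm^3 outside the configured range [{lo}, {hi}] cm^3"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    voxvol = spec.voxel_volume_cm3
    n_target = int(round(volume_cm3 / voxvol))
    if n_target < spec.min_voxel_floor:
        raise ValueError(
            f"requested volume {volume_cm3} cm^3 holds only {n_target} voxels, "
            f"below the configured floor of {spec.min_voxel_floor} voxels"
        )

    # mildly anisotropic ellipsoid with the requested volume
    factors = rng.uniform(0.75, 1.3, size=3)
    factors /= np.prod(factors) ** (1.0 / 3.0)
    r_base_mm = (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    semi_mm = r_base_mm * factors
    spacing = np.asarray(spec.voxel_spacing_mm)
    shape = tuple(int(2 * math.ceil(s / sp) + 5) for s, sp in zip(semi_mm, spacing))
    center = (np.asarray(shape) - 1) / 2.0 * spacing
    idx = np.indices(shape, dtype=np.float64)
    d2 = sum(
        ((idx[k] * spacing[k] - center[k]) / semi_mm[k]) ** 2 for k in range(3)
    )
    order = np.argsort(d2.ravel(), kind="stable")[:n_target]
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[order] = True

    suv_mean = rng.uniform(*spec.lesion_suv_mean_range)
    band_lo = suv_mean * (1.0 - spec.lesion_contrast_fraction)
    band_hi = suv_mean * (1.0 + spec.lesion_contrast_fraction)
    white_coarse = rng.standard_normal(shape)
    white_fine = rng.standard_normal(shape)
    values = np.full(shape, float(spec.background_suv))
    if heterogeneity_h <= H_MIN:
        values[mask] = suv_mean
    else:
        coarse = gaussian_filter(white_coarse, sigma=COARSE_SIGMA)
        coarse /= coarse.std()
        field = coarse + _fine_weight(heterogeneity_h) * white_fine
        # rank (copula) rescaling to the SUV band: uniform level occupancy,
        # so quantized texture reflects spatial correlation only
        ranks = sps.rankdata(field[mask], method="ordinal")
        values[mask] = band_lo + (ranks - 1.0) / max(ranks.size - 1.0, 1.0) * (
            band_hi - band_lo
        )
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)

    volume = PETVolume(values=values, spacing_mm=spec.voxel_spacing_mm, unit="SUV")
    voi = VOIMask(mask=mask, patient_id=patient_id, site=site, lesion_id=lesion_id)
    return volume, voi


def _draw_clinical(spec: PhantomSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-patient latents and pre/post marker values via the copula."""
    n = spec.n_patients
    h = rng.standard_normal(n)
    rows = {"h": h}
    links = {
        "psa": (spec.heterogeneity_link_rho, spec.responder_fraction_target),
        "ap": (spec.ap_link_rho, spec.ap_responder_fraction),
        "bap": (spec.bap_link_rho, spec.bap_responder_fraction),
    }
    for marker, (rho, frac) in links.items():
        delta = _linked_deltas(h, rho, frac, marker, rng)
        pre = _pre_values(delta, marker, rng)
        rows[f"pre_{marker}"] = pre
        rows[f"post_{marker}"] = pre + delta
        rows[f"delta_{marker}"] = delta
    ecog = rng.choice([0, 1, 2], size=n, p=[0.3, 0.5, 0.2])
    rows["ecog_pre"] = ecog
    rows["ecog_post"] = ecog.copy()  # no ECOG change in the default generator
    df = pd.DataFrame(rows)
    df.insert(0, "patient_id", [f"P{i:03d}" for i in range(n)])
    return df


def _lesion_sites(spec: PhantomSpec, rng: np.random.Generator) -> list[str]:
    sites = ["bone"] * spec.n_bone
    if rng.random() < spec.p_lymph_node:
        sites += ["lymph_node"] * spec.n_lymph_node
    if rng.random() < spec.p_other:
        sites += ["other"] * int(rng.integers(1, spec.max_other + 1))
    return sites


def generate_cohort(spec: PhantomSpec, with_images: bool = True) -> CohortBundle:
    """Generate a full synthetic cohort from one seed.

    Every patient has bone lesions; lymph-node and other lesions appear with
    their configured probabilities. Lesion volumes are drawn independently
    of the latent heterogeneity. ``with_images=False`` skips image synthesis
    and returns an empty lesion list (clinical + latents only).
    """
    rng = np.random.default_rng(spec.seed)
    patients = _draw_clinical(spec, rng)

    lesions: list[LesionRecord] = []
    clin_rows = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        for j, site in enumerate(_lesion_sites(spec, rng)):
            lesion_id = f"L{j}"
            vol_cm3 = rng.uniform(*spec.lesion_volume_range_cm3)
            if with_images:
                volume, mask = generate_lesion_image(
                    vol_cm3, row["h"], spec, rng,
                    patient_id=pid, site=site, lesion_id=lesion_id,
                )
                lesions.append(
                    LesionRecord(pid, site, lesion_id, vol_cm3, volume, mask, row["h"])
                )
            clin_rows.append(
                {
                    "patient_id": pid,
                    "site": site,
                    "lesion_id": lesion_id,
                    **{
                        c: row[c]
                        for c in (
                            "pre_psa", "post_psa", "pre_ap", "post_ap",
                            "pre_bap", "post_bap",
                        )
                    },
                    "ecog_pre": int(row["ecog_pre"]),
                    "ecog_post": int(row["ecog_post"]),
                }
            )
    clinical = pd.DataFrame(clin_rows, columns=CLINICAL_COLUMNS)
    truth = patients[["patient_id", "h", "delta_psa"]].copy()
    return CohortBundle(lesions=lesions, clinical=clinical, ground_truth=truth, spec=spec)


def generate_fast_cohort(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fast path: emit patient-level feature values straight from the copula.

    Skips image synthesis entirely, for statistical tests needing thousands
    of replicates. Entropy and homogeneity are deterministic monotone
    transforms of the latent ``h`` (increasing and decreasing respectively),
    so their rank link to the PSA delta equals the configured target; the
    remaining features and lesion volume are drawn independently of ``h``
    (null links). Returns ``(patient_features, clinical, ground_truth)``
    shaped like the image path's outputs after aggregation.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    patients = _draw_clinical(spec, rng)
    n = spec.n_patients
    ph = sps.norm.cdf(patients["h"].to_numpy())
    features = pd.DataFrame(
        {
            "patient_id": patients["patient_id"],
            "site": "bone",
            "volume_cm3": rng.uniform(*spec.lesion_volume_range_cm3, size=n),
            "suv_mean": np.exp(rng.normal(math.log(8.0), 0.3, size=n)),
            "cov": np.abs(rng.normal(0.30, 0.08, size=n)) + 0.02,
            "entropy": 4.0 + 2.0 * ph,
            "homogeneity": 0.65 - 0.35 * ph,
            "contrast": np.exp(rng.normal(math.log(40.0), 0.4, size=n)),
            "size_variation": np.abs(rng.normal(2.0, 0.5, size=n)) + 0.1,
            "n_lesions": spec.n_bone,
        }
    )
    clin_cols = [
        "patient_id", "pre_psa", "post_psa", "pre_ap", "post_ap",
        "pre_bap", "post_bap", "ecog_pre", "ecog_post",
    ]
    clinical = patients[clin_cols].copy()
    clinical.insert(1, "site", "bone")
    clinical.insert(2, "lesion_id", "L0")
    truth = patients[["patient_id", "h", "delta_psa"]].copy()
    return features, clinical, truth
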