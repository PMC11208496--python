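"""Synthetic cohorts with a planted poor-prognosis subgroup.

The generator emulates the structure of a two-subtype endometrial carcinoma
cohort (NSMP vs p53abn) in which a fraction of molecularly-NSMP patients is
latently "p53abn-like": their slide-level bags of patch embeddings are drawn
from the p53abn embedding distribution and their survival follows the
p53abn-like hazard, while their molecular label remains NSMP.  Every
downstream stage — MIL training, ensemble consensus, survival and
copy-number-burden comparisons — is therefore testable without any slide
data.

Embedding model: each bag of size k ~ U[k_min, k_max] holds
ceil(signal_fraction * k) class-informative patches ~ N(mu_group, I) and the
remainder ~ N(mu_bg, I), with mu_bg at the midpoint of the class means so
that signal_fraction is the only knob for bag-level separability.
Survival: exponential event times with group hazards, uniform censoring on
[0, censor_horizon].  Copy-number: a fixed synthetic genome tiled into bins,
with each patient's altered fraction drawn from a group Beta distribution.

Randomness: a single root seed expands into per-patient substreams via
``np.random.SeedSequence(seed, spawn_key=...)`` so cohorts are reproducible
regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .varmil import PatchBag

__all__ = [
    "GROUP_NSMP",
    "GROUP_P53ABN_LIKE",
    "GROUP_P53ABN",
    "SynthConfig",
    "CohortRecord",
    "SynthCohort",
    "gen_cohort",
    "gen_bag",
    "gen_survival",
    "gen_segments",
    "gen_patch_image",
    "two_stain_concentration_field",
    "write_cohort_csv",
    "write_embeddings_h5",
    "read_embeddings_h5",
    "write_segments_tsv",
]

GROUP_NSMP = "NSMP"
GROUP_P53ABN_LIKE = "p53abn-like NSMP"
GROUP_P53ABN = "p53abn"
GROUPS = (GROUP_NSMP, GROUP_P53ABN_LIKE, GROUP_P53ABN)

# covariate rates per latent group: (high grade, stage III-IV,
# non-endometrioid histotype, age >= 60); loosely calibrated to published
# clinicopathologic tables for NSMP/p53abn, with the p53abn-like group
# enriched for higher grade and stage
_COVARIATE_RATES = {
    GROUP_NSMP: (0.08, 0.10, 0.02, 0.59),
    GROUP_P53ABN_LIKE: (0.50, 0.30, 0.10, 0.70),
    GROUP_P53ABN: (0.87, 0.45, 0.73, 0.88),
}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort."""

    n_nsmp: int = 200
    n_p53abn: int = 100
    planted_fraction: float = 0.2
    embed_dim: int = 16
    class_separation: float = 2.0
    signal_fraction: float = 0.5
    bag_size_range: tuple[int, int] = (30, 60)
    hazard_rates: dict[str, float] = field(default_factory=lambda: {
        GROUP_NSMP: 0.03, GROUP_P53ABN_LIKE: 0.09, GROUP_P53ABN: 0.10,
    })
    censor_horizon: float = 10.0
    fga_beta_params: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        GROUP_NSMP: (2.0, 18.0),
        GROUP_P53ABN_LIKE: (3.5, 6.5),
        GROUP_P53ABN: (5.5, 4.5),
    })
    genome_chroms: int = 22
    bins_per_chrom: int = 100
    bin_size: int = 1_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_nsmp < 1:
            raise ValueError("n_nsmp must be a positive integer")
        if self.n_p53abn < 1:
            raise ValueError("n_p53abn must be a positive integer")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be a positive integer")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if not 0.0 < self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in (0, 1]")
        k_min, k_max = self.bag_size_range
        if k_min < 1 or k_max < k_min:
            raise ValueError("bag_size_range must satisfy 1 <= k_min <= k_max")
        for g in GROUPS:
            if self.hazard_rates.get(g, 0.0) <= 0:
                raise ValueError(f"hazard_rates[{g!r}] must be strictly positive")
            a, b = self.fga_beta_params.get(g, (0.0, 0.0))
            if a <= 0 or b <= 0:
                raise ValueError(f"fga_beta_params[{g!r}] must be strictly positive")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")

    # class means: symmetric about the origin along a fixed direction, with
    # the background distribution at the midpoint (origin)
    def group_mean(self, group: str) -> np.ndarray:
        u = np.ones(self.embed_dim) / math.sqrt(self.embed_dim)
        half = 0.5 * self.class_separation
        if group == GROUP_NSMP:
            return -half * u
        if group in (GROUP_P53ABN, GROUP_P53ABN_LIKE):
            return half * u
        raise ValueError(f"unknown group {group!r}")

    def background_mean(self) -> np.ndarray:
        return np.zeros(self.embed_dim)


@dataclass
class CohortRecord:
    patient_id: str
    subtype: str               # molecular label: NSMP or p53abn
    grade: str                 # "G1-2" / "G3"
    stage: str                 # "I-II" / "III-IV"
    histotype: str             # "endometrioid" / "non-endometrioid"
    age_ge_60: int
    pfs_time: float
    pfs_event: int
    dss_time: float
    dss_event: int


@dataclass
class SynthCohort:
    config: SynthConfig
    records: list[CohortRecord]
    bags: list[PatchBag]
    segments: dict[str, pd.DataFrame]
    truth: dict[str, str]

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def molecular_labels(self) -> dict[str, str]:
        return {r.patient_id: r.subtype for r in self.records}


def _patient_rng(config: SynthConfig, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(index, stream))
    )


def gen_bag(group: str, config: SynthConfig, rng: np.random.Generator,
            slide_id: str = "S", patient_id: str = "P") -> PatchBag:
    """One slide bag: signal patches from the group's embedding distribution,
    the rest from the shared background; p53abn-like bags are identical in
    law to p53abn bags."""
    config.validate()
    k_min, k_max = config.bag_size_range
    k = int(rng.integers(k_min, k_max + 1))
    n_sig = math.ceil(config.signal_fraction * k)
    mu = config.group_mean(group)
    Z = np.vstack([
        rng.normal(size=(n_sig, config.embed_dim)) + mu,
        rng.normal(size=(k - n_sig, config.embed_dim)) + config.background_mean(),
    ])
    rng.shuffle(Z, axis=0)
    return PatchBag(Z=Z, slide_id=slide_id, patient_id=patient_id)


def gen_survival(group: str, config: SynthConfig,
                 rng: np.random.Generator) -> tuple[float, int]:
    """Exponential event time with the group hazard, uniform censoring."""
    lam = config.hazard_rates[group]
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(0.0, config.censor_horizon)
    if t_event <= t_censor:
        return float(t_event), 1
    return float(t_censor), 0


def gen_segments(group: str, config: SynthConfig, rng: np.random.Generator,
                 sample: str = "S") -> pd.DataFrame:
    """SEG-style table tiling the synthetic genome, one row per bin.

    The altered fraction is drawn from the group's Beta distribution and
    realized by flagging round(f * n_bins) bins; altered bins get
    |log2ratio| >= 0.25, unaltered bins stay within (-0.19, 0.19).
    """
    a, b = config.fga_beta_params[group]
    f = rng.beta(a, b)
    n_bins = config.genome_chroms * config.bins_per_chrom
    n_alt = int(round(f * n_bins))
    altered = np.zeros(n_bins, dtype=int)
    if n_alt > 0:
        altered[rng.choice(n_bins, size=n_alt, replace=False)] = 1

    log2 = np.clip(rng.normal(0.0, 0.05, size=n_bins), -0.19, 0.19)
    n_altered = int(altered.sum())
    signs = rng.choice([-1.0, 1.0], size=n_altered)
    log2[altered == 1] = signs * (0.25 + rng.exponential(0.3, size=n_altered))

    chrom = np.repeat(np.arange(1, config.genome_chroms + 1), config.bins_per_chrom)
    start = np.tile(
        np.arange(config.bins_per_chrom) * config.bin_size, config.genome_chroms
    )
    return pd.DataFrame({
        "sample": sample,
        "chrom": [f"chr{c}" for c in chrom],
        "start": start,
        "end": start + config.bin_size,
        "log2ratio": np.round(log2, 4),
        "altered_flag": altered,
    })


def _gen_covariates(group: str, rng: np.random.Generator) -> tuple[str, str, str, int]:
    p_grade, p_stage, p_histo, p_age = _COVARIATE_RATES[group]
    grade = "G3" if rng.random() < p_grade else "G1-2"
    stage = "III-IV" if rng.random() < p_stage else "I-II"
    histo = "non-endometrioid" if rng.random() < p_histo else "endometrioid"
    age = int(rng.random() < p_age)
    return grade, stage, histo, age


def gen_cohort(config: SynthConfig) -> SynthCohort:
    """Full synthetic cohort: records, embedding bags, segment tables and the
    latent truth map.  Deterministic given ``config.seed``."""
    config.validate()
    n_planted = int(round(config.planted_fraction * config.n_nsmp))
    n_total = config.n_nsmp + config.n_p53abn

    cohort_rng = _patient_rng(config, 2**20, 0)
    planted_idx = set(
        cohort_rng.choice(config.n_nsmp, size=n_planted, replace=False).tolist()
    )

    records: list[CohortRecord] = []
    bags: list[PatchBag] = []
    segments: dict[str, pd.DataFrame] = {}
    truth: dict[str, str] = {}

    for i in range(n_total):
        pid = f"P{i + 1:04d}"
        if i < config.n_nsmp:
            group = GROUP_P53ABN_LIKE if i in planted_idx else GROUP_NSMP
            molecular = GROUP_NSMP
        else:
            group = GROUP_P53ABN
            molecular = GROUP_P53ABN
        truth[pid] = group

        bag_rng = _patient_rng(config, i, 1)
        bags.append(gen_bag(group, config, bag_rng,
                            slide_id=f"{pid}-S1", patient_id=pid))

        surv_rng = _patient_rng(config, i, 2)
        pfs_time, pfs_event = gen_survival(group, config, surv_rng)
        dss_time, dss_event = gen_survival(group, config, surv_rng)

        cov_rng = _patient_rng(config, i, 3)
        grade, stage, histo, age = _gen_covariates(group, cov_rng)
        records.append(CohortRecord(
            patient_id=pid, subtype=molecular, grade=grade, stage=stage,
            histotype=histo, age_ge_60=age,
            pfs_time=pfs_time, pfs_event=pfs_event,
            dss_time=dss_time, dss_event=dss_event,
        ))

        seg_rng = _patient_rng(config, i, 4)
        segments[pid] = gen_segments(group, config, seg_rng, sample=pid)

    return SynthCohort(config=config, records=records, bags=bags,
                       segments=segments, truth=truth)


# ---------------------------------------------------------------------------
# two-stain Beer-Lambert patch images


def two_stain_concentration_field(
    height: int, width: int, rng: np.random.Generator,
    n_blobs: int = 6, max_conc: float = 1.2,
) -> np.ndarray:
    """Smooth nonnegative (H, W, 2) concentration field made of Gaussian blobs,
    loosely emulating nuclear (hematoxylin) and cytoplasmic (eosin) regions."""
    yy, xx = np.mgrid[0:height, 0:width]
    C = np.zeros((height, width, 2))
    for s in range(2):
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, height), rng.uniform(0, width)
            sig = rng.uniform(0.08, 0.25) * min(height, width)
            amp = rng.uniform(0.3, max_conc)
            C[..., s] += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    return C


def gen_patch_image(
    stain_matrix: np.ndarray,
    concentrations: np.ndarray,
    rng: np.random.Generator | None = None,
    noise_level: float = 0.0,
    I0: float = 255.0,
) -> np.ndarray:
    """Render an RGB patch by the Beer-Lambert law, I = I0 * 10^(-S c).

    ``stain_matrix`` is 3x2 with nonnegative unit-norm columns;
    ``concentrations`` is (H, W, 2) and must be nonnegative.  Optional bounded
    uniform noise (in intensity levels) is added before quantization.
    """
    S = np.asarray(stain_matrix, dtype=np.float64)
    C = np.asarray(concentrations, dtype=np.float64)
    if S.shape != (3, 2) or np.any(S < 0):
        raise ValueError("stain matrix must be 3x2 with nonnegative entries")
    if C.ndim != 3 or C.shape[2] != 2:
        raise ValueError("concentration field must have shape (H, W, 2)")
    if np.any(C < 0):
        raise ValueError("concentrations must be nonnegative")
    od = C @ S.T
    img = I0 * np.power(10.0, -od)
    if noise_level > 0:
        if rng is None:
            raise ValueError("rng required when noise_level > 0")
        img = img + rng.uniform(-noise_level, noise_level, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# writers (plain-text cohort CSV, HDF5 embedding store, SEG TSV)


def write_cohort_csv(cohort: SynthCohort, path: str | Path) -> None:
    cohort.records_frame().to_csv(path, index=False)


def write_embeddings_h5(cohort: SynthCohort, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for bag in cohort.bags:
            ds = f.create_dataset(bag.slide_id, data=bag.Z)
            ds.attrs["patient_id"] = bag.patient_id


def read_embeddings_h5(path: str | Path) -> list[PatchBag]:
    bags = []
    with h5py.File(path, "r") as f:
        for slide_id in sorted(f.keys()):
            ds = f[slide_id]
            bags.append(PatchBag(Z=ds[...], slide_id=slide_id,
                                 patient_id=str(ds.attrs["patient_id"])))
    return bags


def write_segments_tsv(cohort: SynthCohort, path: str | Path) -> None:
    pd.concat(cohort.segments.values(), ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
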