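"""Synthetic two-block metabolomics data with a planted cross-block signature.

The generator emulates the structure of a small two-arm plasma metabolomics
study: an NMR bucket table (~102 variables, several buckets per metabolite,
strongly correlated within a metabolite), a lipid intensity table (~290
species), and a clinical table with no planted group differences. A small set
of informative features — by default 7 polar metabolites spanning 10 NMR
buckets (one metabolite contributes 4 buckets) plus 2 lipids — loads on a
per-sample latent factor that carries the class effect, so the discriminative
signal is shared across blocks.

Model, on the log-intensity scale. A per-sample disease axis carries the
class effect into a per-block latent factor

    L_b,i = (effect / alpha) * c_i + sqrt(r_b) F_i + sqrt(1 - r_b) G_b,i

with c_i the centered class indicator and F a standard-normal factor shared
across blocks (r_b = ``block_corr``), so informative features of the two
blocks are correlated with each other *through the same class-bearing
latent* — the structure a multiblock integration method exploits. Each
informative feature j of metabolite m in block b loads on this latent with a
per-metabolite sign s_m:

    z_ij = s_m * alpha * L_b,i + beta g_m,i + gamma e_ij

with g_m a per-metabolite shared noise and e_ij idiosyncratic noise. The
variance split

    alpha^2 = 1 / (1 + noise_sd^2),   alpha^2 + beta^2 = rho,
    gamma^2 = 1 - rho

makes the within-class feature variance exactly 1 — so every informative
feature's class-mean difference is exactly ``effect_size`` in feature-SD
units, the parameter's definition — and makes the
within-metabolite bucket correlation exactly rho (requires rho >= alpha^2;
the constructor rejects parameter combinations whose implied correlation
matrix is not positive semi-definite). Uninformative features are
independent standard normal. Intensities are x = exp(kappa z + b_j) with a
fixed per-feature baseline b_j and a global log-scale kappa keeping the
log-normal skew mild — strictly positive, so total-intensity normalization
and fold changes behave as on real bucket tables.

Ground truth (which feature ids are informative) is returned separately from
the dataset so no pipeline stage can accidentally read it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .data import DECLINE, NO_DECLINE, MultiBlockDataset, OmicsBlock, SampleTable

__all__ = ["SimulationSpec", "generate_dataset", "generate_clinical_table"]


@dataclass
class SimulationSpec:
    """Study-design parameters of the generator (defaults mirror the study:
    12 non-decliners vs 8 decliners, 102 NMR buckets, 290 lipids, 9 planted
    metabolites of which one spans 4 buckets)."""

    n_per_class: tuple[int, int] = (12, 8)  # (NoDecline, Decline)
    p_nmr: int = 102
    p_lipid: int = 290
    planted_nmr_metabolites: int = 7
    buckets_per_metabolite: tuple[int, ...] = (4, 1, 1, 1, 1, 1, 1)
    planted_lipids: int = 2
    effect_size: float = 1.5
    within_metabolite_corr: float = 0.9
    block_corr: float = 0.7
    noise_sd: float = 1.0
    log_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.buckets_per_metabolite) != self.planted_nmr_metabolites:
            raise ValueError(
                "buckets_per_metabolite length must equal planted_nmr_metabolites"
            )
        if sum(self.buckets_per_metabolite) > self.p_nmr:
            raise ValueError("planted buckets exceed p_nmr")
        if self.planted_lipids > self.p_lipid:
            raise ValueError("planted lipids exceed p_lipid")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.within_metabolite_corr < 1):
            raise ValueError("within_metabolite_corr must be in [0, 1)")
        if not (0 <= self.block_corr < 1):
            raise ValueError("block_corr must be in [0, 1)")
        if self.within_metabolite_corr < self.latent_share:
            raise ValueError(
                "implied correlation matrix not positive semi-definite: "
                f"within_metabolite_corr={self.within_metabolite_corr} < "
                f"latent share 1/(1+noise_sd^2)={self.latent_share:.3f}"
            )

    @property
    def latent_share(self) -> float:
        """Fraction of informative-feature noise variance carried by the
        block latent (alpha^2)."""
        return 1.0 / (1.0 + self.noise_sd**2)


_LIPID_CLASSES = ["PC", "PE", "TG", "DG", "CE", "Cer", "LPC", "LPE", "FA", "PI"]


def _nmr_feature_ids(p: int, rng: np.random.Generator) -> list[str]:
    """Chemical-shift-like labels between 0.7 and 8.5 ppm, unique, sorted
    downfield-first as NMR bucket tables usually are."""
    shifts = np.sort(rng.uniform(0.7, 8.5, size=p))[::-1]
    ids = [f"{s:.4f}" for s in shifts]
    while len(set(ids)) != p:  # regenerate collisions (4 d.p. space is ample)
        shifts = np.sort(rng.uniform(0.7, 8.5, size=p))[::-1]
        ids = [f"{s:.4f}" for s in shifts]
    return ids


def _lipid_feature_ids(p: int, rng: np.random.Generator) -> list[str]:
    ids: list[str] = ["SM_d18.1_C26.0", "TG_48.3"]
    seen = set(ids)
    while len(ids) < p:
        cls = _LIPID_CLASSES[rng.integers(len(_LIPID_CLASSES))]
        name = f"{cls}_{rng.integers(24, 60)}.{rng.integers(0, 7)}"
        if name not in seen:
            seen.add(name)
            ids.append(name)
    return ids


def generate_clinical_table(
    n_per_class: tuple[int, int] = (12, 8),
    seed: int = 0,
    decline_threshold: int = 2,
    follow_up_years: int = 4,
) -> SampleTable:
    """Clinical table with null covariates and class-consistent MMSE series.

    Covariates (age, sex, BMI, comorbidity flags, depression score) are drawn
    from the same distribution for both classes — the all-nonsignificant
    baseline of a matched exploratory study. MMSE trajectories are built so
    that decliners drop at least ``decline_threshold`` points from first to
    last visit and non-decliners drop less, so the decliner rule recovers the
    generating classes exactly.
    """
    n0, n1 = n_per_class
    if n0 < 1 or n1 < 1:
        raise ValueError("need >= 1 sample per class")
    rng = substream(seed, "clinical")
    n = n0 + n1
    ids = [f"S{i + 1:02d}" for i in range(n)]
    groups = [NO_DECLINE] * n0 + [DECLINE] * n1

    cov = pd.DataFrame(
        {
            "age": np.round(rng.normal(77.0, 5.4, n), 1),
            "sex": rng.choice(["F", "M"], n),
            "bmi": np.round(rng.normal(25.7, 2.6, n), 1),
            "hypertension": rng.random(n) < 0.5,
            "diabetes": rng.random(n) < 0.15,
            "gds": np.clip(np.round(rng.normal(3.1, 2.3, n)), 0, 15).astype(int),
        },
        index=pd.Index(ids),
    )

    times = [float(t) for t in range(follow_up_years + 1)]
    mmse: dict[str, list[tuple[float, float]]] = {}
    for sid, g in zip(ids, groups):
        first = float(np.clip(np.round(rng.normal(27.0, 1.6)), 24, 30))
        if g == DECLINE:
            drop = decline_threshold + int(rng.integers(0, 4))
        else:
            drop = int(rng.integers(-1, decline_threshold))  # < threshold
        last = float(np.clip(first - drop, 0, 30))
        if first - last < decline_threshold and g == DECLINE:
            first = min(30.0, last + decline_threshold)  # clip pushed last up
        inner = np.linspace(first, last, len(times))
        jitter = rng.integers(-1, 2, len(times)).astype(float)
        jitter[0] = jitter[-1] = 0.0
        scores = np.clip(np.round(inner + jitter), 0, 30)
        scores[0], scores[-1] = first, last
        mmse[sid] = list(zip(times, [float(s) for s in scores]))

    return SampleTable(
        ids,
        group=pd.Series(groups, index=pd.Index(ids)),
        mmse_series=mmse,
        covariates=cov,
    )


def generate_dataset(
    spec: SimulationSpec,
) -> tuple[MultiBlockDataset, dict[str, list[str]]]:
    """Generate a two-block dataset plus the ground-truth informative ids.

    Returns ``(dataset, truth)`` where ``truth`` maps block name -> list of
    informative feature ids (and ``"metabolites"`` -> metabolite-level names).
    """
    rng = substream(spec.seed, "synthetic")
    n0, n1 = spec.n_per_class
    n = n0 + n1
    samples = generate_clinical_table(spec.n_per_class, spec.seed)
    y = (samples.group.to_numpy() == DECLINE).astype(float)
    c = y - y.mean()

    shared = rng.standard_normal(n)
    alpha = np.sqrt(spec.latent_share)
    beta = np.sqrt(spec.within_metabolite_corr - spec.latent_share)
    gamma = np.sqrt(1.0 - spec.within_metabolite_corr)
    gamma_single = np.sqrt(1.0 - spec.latent_share)  # lone features: no g_m term

    def block_latent() -> np.ndarray:
        own = rng.standard_normal(n)
        return (
            (spec.effect_size / alpha) * c
            + np.sqrt(spec.block_corr) * shared
            + np.sqrt(1.0 - spec.block_corr) * own
        )

    def noise_block(n_feat: int) -> np.ndarray:
        return rng.standard_normal((n, n_feat))

    # ---- NMR block ----
    nmr_ids = _nmr_feature_ids(spec.p_nmr, rng)
    n_buckets = sum(spec.buckets_per_metabolite)
    planted_pos = rng.choice(spec.p_nmr, size=n_buckets, replace=False)
    z_nmr = noise_block(spec.p_nmr)
    L_nmr = block_latent()
    annotation: dict[str, str] = {}
    nmr_truth: list[str] = []
    met_names: list[str] = []
    k = 0
    for m, width in enumerate(spec.buckets_per_metabolite):
        met = f"met{m + 1:02d}"
        met_names.append(met)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        g_m = rng.standard_normal(n)
        for _ in range(width):
            j = planted_pos[k]
            e = rng.standard_normal(n)
            z_nmr[:, j] = sign * alpha * L_nmr + beta * g_m + gamma * e
            annotation[nmr_ids[j]] = met
            nmr_truth.append(nmr_ids[j])
            k += 1

    # ---- lipid block ----
    lipid_ids = _lipid_feature_ids(spec.p_lipid, rng)
    z_lip = noise_block(spec.p_lipid)
    L_lip = block_latent()
    lipid_truth: list[str] = []
    lip_pos = rng.choice(spec.p_lipid, size=spec.planted_lipids, replace=False)
    for j in lip_pos:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        e = rng.standard_normal(n)
        z_lip[:, j] = sign * alpha * L_lip + gamma_single * e
        lipid_truth.append(lipid_ids[j])

    def to_intensity(z: np.ndarray) -> np.ndarray:
        baselines = rng.standard_normal(z.shape[1])
        return np.exp(spec.log_scale * z + baselines)

    nmr = OmicsBlock("nmr", nmr_ids, to_intensity(z_nmr), annotation)
    lipid = OmicsBlock("lipid", lipid_ids, to_intensity(z_lip))
    dataset = MultiBlockDataset(samples, [nmr, lipid])
    truth = {
        "nmr": nmr_truth,
        "lipid": lipid_truth,
        "metabolites": met_names + lipid_truth,
    }
    return dataset, truth
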