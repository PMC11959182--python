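"""Synthetic metagenomics count data with known differential-abundance truth.

The generative scheme mirrors how sequencing experiments actually produce
counts: each taxon's absolute abundance in a sample follows a
zero-inflated log-normal distribution (a per-taxon presence probability
times a log-normal abundance when present), library sizes follow a
log-normal distribution whose mean may differ between conditions, and the
observed counts are a multinomial draw of the library size over the
sample's relative abundances.  Differentially abundant taxa shift both
their presence probability and their log-mean between conditions so that
the *total* absolute-abundance fold change equals the configured value.
Because counts are compositional, DA taxa perturb every taxon's relative
abundance — the situation the reference-normalization machinery exists to
untangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CountTable

__all__ = [
    "ScenarioConfig",
    "TrueAbundanceProfile",
    "simulate_true_profile",
    "simulate_counts",
    "simulate_dataset",
    "make_toy_example",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    ``mean_library_size`` may be a scalar (balanced) or a per-condition
    pair such as ``(1e4, 1e5)`` (unbalanced sequencing depth).
    ``direction`` controls whether DA taxa are enriched and depleted in
    equal numbers (``"balanced"``) or all shifted the same way
    (``"unbalanced"``).  The hyperpriors (log-mean ~ N(0, 2), log-sd ~
    U(0.5, 2), baseline zero-inflation ~ U(0.2, 0.8)) produce the 60-80%
    sparsity typical of 16S count tables.
    """

    n_taxa: int = 100
    n_samples: int = 100
    da_proportion: float = 0.1
    mean_fold_change: float = 5.0
    direction: str = "unbalanced"
    mean_library_size: float | tuple[float, float] = 1e4
    library_size_log_sd: float = 0.5
    zero_inflation_range: tuple[float, float] = (0.2, 0.8)
    log_mean_sd: float = 2.0
    log_sd_range: tuple[float, float] = (0.5, 2.0)
    confounder_effect: float = 0.0
    confounder_rho: float = 0.5
    confounder_taxa_fraction: float = 0.1
    taxa_correlation: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.da_proportion < 1:
            raise ValueError("da_proportion must lie in [0, 1)")
        if self.mean_fold_change <= 0:
            raise ValueError("mean_fold_change must be positive")
        if self.direction not in ("balanced", "unbalanced"):
            raise ValueError("direction must be 'balanced' or 'unbalanced'")
        libs = self.library_size_means()
        if any(m <= 0 for m in libs):
            raise ValueError("library sizes must be positive")
        if not 0 <= self.taxa_correlation < 1:
            raise ValueError("taxa_correlation must lie in [0, 1)")

    def library_size_means(self) -> tuple[float, float]:
        m = self.mean_library_size
        if np.isscalar(m):
            return (float(m), float(m))
        return (float(m[0]), float(m[1]))


@dataclass
class TrueAbundanceProfile:
    """Ground-truth abundance parameters for both conditions.

    ``absolute[j, g]`` is the expected absolute abundance of taxon j in
    condition g (presence probability times the log-normal mean) and
    ``relative`` its within-condition share.  ``log_fold[j]`` is the true
    natural-log absolute-abundance fold change (0 for non-DA taxa).
    """

    log_means: np.ndarray  # (P, 2)
    log_sds: np.ndarray  # (P,)
    zero_probs: np.ndarray  # (P, 2)
    da_flags: np.ndarray  # (P,) bool
    log_fold: np.ndarray  # (P,)
    taxon_ids: list[str] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return self.log_means.shape[0]

    @property
    def absolute(self) -> np.ndarray:
        present = 1.0 - self.zero_probs
        return present * np.exp(self.log_means + 0.5 * self.log_sds[:, None] ** 2)

    @property
    def relative(self) -> np.ndarray:
        a = self.absolute
        return a / a.sum(axis=0, keepdims=True)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_true_profile(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> TrueAbundanceProfile:
    """Draw per-taxon abundance parameters and plant the DA signal.

    Exactly round(P * da_proportion) taxa are flagged DA.  Each DA taxon's
    presence logit is shifted by the signed log fold change and its
    log-mean by the remainder, so its expected absolute abundance changes
    by exactly the configured fold.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    P = cfg.n_taxa
    base_mean = rng.normal(0.0, cfg.log_mean_sd, size=P)
    log_sds = rng.uniform(*cfg.log_sd_range, size=P)
    base_zero = rng.uniform(*cfg.zero_inflation_range, size=P)

    n_da = int(round(P * cfg.da_proportion))
    da_flags = np.zeros(P, dtype=bool)
    log_fold = np.zeros(P)
    if n_da:
        da_idx = rng.choice(P, size=n_da, replace=False)
        da_flags[da_idx] = True
        signs = np.ones(n_da)
        if cfg.direction == "balanced":
            signs[1::2] = -1.0
        log_fold[da_idx] = signs * np.log(cfg.mean_fold_change)

    zero2 = base_zero.copy()
    mean2 = base_mean.copy()
    if n_da:
        da = da_flags
        # presence responds to the shift; the log-mean absorbs the rest so
        # that (1-p2)/(1-p1) * exp(mean shift) == fold change exactly
        zero2[da] = _sigmoid(_logit(base_zero[da]) - log_fold[da])
        presence_lf = np.log1p(-zero2[da]) - np.log1p(-base_zero[da])
        mean2[da] = base_mean[da] + (log_fold[da] - presence_lf)

    return TrueAbundanceProfile(
        log_means=np.column_stack([base_mean, mean2]),
        log_sds=log_sds,
        zero_probs=np.column_stack([base_zero, zero2]),
        da_flags=da_flags,
        log_fold=log_fold,
        taxon_ids=[f"taxon_{j + 1}" for j in range(P)],
    )


def simulate_counts(
    profile: TrueAbundanceProfile,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame]:
    """Draw a count table, metadata, and per-taxon truth table.

    Samples are split evenly between conditions.  Per sample, taxa are
    silenced by their condition's zero-inflation probability, abundances
    of present taxa are log-normal (optionally sharing a Gaussian-copula
    factor across taxa), the library size is log-normal with the
    condition's mean, and counts are multinomial — so each sample's counts
    sum exactly to its library size.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    P, N = profile.n_taxa, cfg.n_samples
    n0 = N // 2
    condition = np.repeat([0, 1], [n0, N - n0])

    confounder = None
    conf_taxa = np.zeros(P, dtype=bool)
    if cfg.confounder_effect != 0.0:
        rho = cfg.confounder_rho
        centered = condition - condition.mean()
        confounder = rho * centered / max(centered.std(), 1e-12) + np.sqrt(
            max(1.0 - rho**2, 0.0)
        ) * rng.normal(size=N)
        n_conf = int(round(P * cfg.confounder_taxa_fraction))
        if n_conf:
            conf_taxa[rng.choice(P, size=n_conf, replace=False)] = True

    mu = profile.log_means[:, condition]  # (P, N)
    sd = profile.log_sds[:, None]
    if confounder is not None:
        mu = mu + cfg.confounder_effect * conf_taxa[:, None] * confounder[None, :]

    if cfg.taxa_correlation > 0:
        shared = rng.normal(size=N)[None, :]
        own = rng.normal(size=(P, N))
        z = np.sqrt(cfg.taxa_correlation) * shared + np.sqrt(
            1.0 - cfg.taxa_correlation
        ) * own
    else:
        z = rng.normal(size=(P, N))
    abundance = np.exp(mu + sd * z)
    present = rng.random((P, N)) >= profile.zero_probs[:, condition]
    abundance *= present

    col_sums = abundance.sum(axis=0)
    dead = col_sums == 0
    if dead.any():  # vanishingly rare; give such samples a flat composition
        abundance[:, dead] = 1.0
        col_sums = abundance.sum(axis=0)
    props = abundance / col_sums

    lib_means = np.asarray(cfg.library_size_means())[condition]
    lib_mu = np.log(lib_means) - 0.5 * cfg.library_size_log_sd**2
    libs = np.maximum(
        1, np.round(rng.lognormal(lib_mu, cfg.library_size_log_sd)).astype(np.int64)
    )

    counts = np.empty((P, N), dtype=np.int64)
    for i in range(N):
        counts[:, i] = rng.multinomial(libs[i], props[:, i])
    # a sample with zero counts everywhere cannot be analyzed; force one read
    empty = counts.sum(axis=0) == 0
    if empty.any():
        counts[0, empty] = 1

    sample_ids = [f"sample_{i + 1}" for i in range(N)]
    ct = CountTable(counts, list(profile.taxon_ids), sample_ids)
    meta = pd.DataFrame({"condition": condition}, index=sample_ids)
    if confounder is not None:
        meta["confounder"] = confounder
    truth = pd.DataFrame(
        {
            "taxon_id": profile.taxon_ids,
            "is_da": profile.da_flags,
            "log_fold_change": profile.log_fold,
            "confounded": conf_taxa,
        }
    ).set_index("taxon_id")
    return ct, meta, truth


def simulate_dataset(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame]:
    """Profile + counts in one call; ``seed`` overrides ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    profile = simulate_true_profile(cfg, rng)
    return simulate_counts(profile, cfg, rng)


def make_toy_example() -> tuple[CountTable, dict]:
    """The seven-taxon, two-sample worked example.

    Sample totals are 21 and 35 reads.  Taxa 6 and 7 are undetected in
    sample one (relative abundance left-censored at 1/21) and taxon 4 is
    undetected in sample two (left-censored at 1/35).  Taxa 1, 4 and 7 are
    differentially abundant; taxa 2, 3 and 5 share the median
    relative-abundance fold change and are the correct reference set.

    Returns the count table and a truth dict with ``da_flags`` and the
    per-taxon ``log_fold_changes`` of relative abundance between the two
    samples (censored entries evaluated at their bounds).
    """
    counts = np.array(
        [
            [6, 2],  # taxon 1: depleted (DA)
            [3, 5],  # taxon 2: reference
            [6, 10],  # taxon 3: reference
            [3, 0],  # taxon 4: vanishes in sample two (DA)
            [3, 5],  # taxon 5: reference
            [0, 5],  # taxon 6: sampling zero in sample one, not DA
            [0, 8],  # taxon 7: appears in sample two (DA)
        ]
    )
    ct = CountTable(
        counts,
        [f"taxon_{j}" for j in range(1, 8)],
        ["sample_1", "sample_2"],
    )
    rel = np.where(counts > 0, counts, 1).astype(float) / counts.sum(axis=0)
    log_fc = np.log(rel[:, 1] / rel[:, 0])
    truth = {
        "da_flags": np.array([True, False, False, True, False, False, True]),
        "log_fold_changes": log_fc,
        "reference_taxa": np.array([1, 2, 4]),  # 0-based indices of taxa 2, 3, 5
    }
    return ct, truth
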