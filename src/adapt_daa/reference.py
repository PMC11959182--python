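"""Reference-taxa selection by iterative halving around the median fold change.

Under the minority-DA assumption, taxa whose relative-abundance fold-change
estimates sit at the median are not differentially abundant, so halving the
taxa set around the median distance repeatedly shrinks it toward a clean
(non-DA) reference set.  Each candidate subset is vetted by refitting Tobit
models to within-subset count proportions and testing the pooled P-values
for right skew; the first subset whose P-values look uniform or left-skewed
is accepted as the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import CensoredCountTable, CovariateDesign
from .skewness import BumFit, test_right_skew
from .tobit import CensoredResponse, TobitConfig, TobitFit, fit_all_taxa

__all__ = [
    "ReferenceSelection",
    "halve_by_median",
    "subset_responses",
    "within_subset_pvalues",
    "select_reference",
    "default_min_reference_size",
]


@dataclass
class HalvingRecord:
    subset_size: int
    reject_uniform: bool
    bum_p_value: float


@dataclass
class ReferenceSelection:
    """Outcome of the iterative halving search for reference taxa."""

    reference_taxa: np.ndarray
    history: list[HalvingRecord] = field(default_factory=list)
    distances: np.ndarray | None = None
    exhausted: bool = False


def default_min_reference_size(n_taxa: int) -> int:
    """Floor on the reference set size: max(10, 5% of taxa).

    A reference of one or two taxa makes the normalization denominator's
    variance explode, so halving is never allowed to shrink past this.
    """
    return max(10, int(np.ceil(0.05 * n_taxa)))


def halve_by_median(estimates: np.ndarray) -> np.ndarray:
    """Indices of the taxa whose estimates are closest to the median.

    Implements the strict rule {k : d_k < median(d)} with
    d_k = |estimate_k - median(estimates)|.  When the strict rule returns
    an empty or more-than-half set (mass ties at the median distance), the
    floor(P/2) smallest-distance taxa are taken instead, remaining ties
    broken by original order; if every distance is identical there is
    nothing to distinguish and all taxa are returned.
    """
    est = np.asarray(estimates, dtype=float)
    if est.ndim != 1 or est.size < 2:
        raise ValueError("need at least two estimates to halve")
    d = np.abs(est - np.median(est))
    if np.ptp(d) == 0:
        return np.arange(est.size)
    med_d = np.median(d)
    strict = np.flatnonzero(d < med_d)
    half = est.size // 2
    if 0 < strict.size <= half:
        return strict
    order = np.argsort(d, kind="stable")
    return np.sort(order[:half])


def subset_responses(
    cct: CensoredCountTable,
    subset: np.ndarray,
    taxa: np.ndarray | None = None,
    use_proxy_denominator: bool = False,
) -> list[CensoredResponse]:
    """Log count-proportion responses of ``taxa`` within a subset denominator.

    For taxon k and sample i the response is log(y*_ik / D_i) with
    D_i the summed raw counts of the subset taxa in sample i (proxied
    counts when ``use_proxy_denominator``).  Censoring indicators come from
    the original zeros; the per-sample censoring bound is log(d / D_i).
    A sample whose denominator is zero has it replaced by the detection
    limit (logged) so the design matrix stays intact.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("denominator subset must be non-empty")
    if taxa is None:
        taxa = subset
    source = cct.proxies if use_proxy_denominator else cct.raw_counts
    denom = source[subset].sum(axis=0)
    n_zero = int(np.sum(denom == 0))
    if n_zero:
        warnings.warn(
            f"{n_zero} sample(s) have a zero subset denominator; "
            "substituting the detection limit",
            RuntimeWarning,
            stacklevel=2,
        )
        denom = np.where(denom == 0, cct.detection_limit, denom)
    log_denom = np.log(denom)
    bound = np.log(cct.detection_limit) - log_denom
    return [
        CensoredResponse(
            values=np.log(cct.proxies[k]) - log_denom,
            indicators=cct.indicators[k],
            bounds=bound,
        )
        for k in taxa
    ]


def within_subset_pvalues(
    cct: CensoredCountTable,
    design: CovariateDesign,
    subset: np.ndarray,
    config: TobitConfig = TobitConfig(),
    use_proxy_denominator: bool = False,
    n_jobs: int = 1,
) -> np.ndarray:
    """LRT P-values of the subset taxa's within-subset count proportions."""
    subset = np.asarray(subset, dtype=int)
    if subset.size < 2:
        raise ValueError("subset must contain at least two taxa")
    responses = subset_responses(
        cct, subset, use_proxy_denominator=use_proxy_denominator
    )
    sub_cct = CensoredCountTable(
        proxies=cct.proxies[subset],
        indicators=cct.indicators[subset],
        detection_limit=cct.detection_limit,
        raw_library_sizes=cct.raw_library_sizes,
    )
    fits = fit_all_taxa(sub_cct, design, responses, config=config, n_jobs=n_jobs)
    return np.array([f.p_value for f in fits])


def select_reference(
    cct: CensoredCountTable,
    design: CovariateDesign,
    stage1_fits: list[TobitFit],
    min_size: int | None = None,
    bum_level: float = 0.05,
    config: TobitConfig = TobitConfig(),
    use_proxy_denominator: bool = False,
    n_jobs: int = 1,
) -> ReferenceSelection:
    """Iteratively halve the taxa set until its P-values stop looking skewed.

    Starts from all taxa (whose pooled stage-1 P-values are assumed to have
    already rejected uniformity), halves around the median fold-change
    estimate, and accepts the first subset whose within-subset P-value
    distribution is uniform or left-skewed.  If halving would drop below
    ``min_size`` without a clean verdict the last subset is returned with
    ``exhausted=True`` instead of raising.
    """
    estimates = np.array([f.tested_estimate for f in stage1_fits])
    if estimates.size != cct.n_taxa:
        raise ValueError("one stage-1 fit per taxon required")
    if min_size is None:
        min_size = default_min_reference_size(cct.n_taxa)
    distances = np.abs(estimates - np.median(estimates))
    subset = np.arange(cct.n_taxa)
    history: list[HalvingRecord] = []
    exhausted = False
    while True:
        candidate = subset[halve_by_median(estimates[subset])]
        if candidate.size >= subset.size:
            # all remaining estimates tied: nothing left to distinguish
            warnings.warn(
                "halving cannot shrink a tied subset; accepting current subset",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        if candidate.size < min_size:
            exhausted = True
            warnings.warn(
                f"reference halving exhausted at size {subset.size} "
                f"(minimum {min_size}) without a clean verdict",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        pvals = within_subset_pvalues(
            cct,
            design,
            candidate,
            config=config,
            use_proxy_denominator=use_proxy_denominator,
            n_jobs=n_jobs,
        )
        verdict: BumFit = test_right_skew(pvals, level=bum_level)
        history.append(
            HalvingRecord(int(candidate.size), verdict.reject_uniform, verdict.p_value)
        )
        subset = candidate
        if not verdict.reject_uniform:
            break
    return ReferenceSelection(
        reference_taxa=subset,
        history=history,
        distances=distances,
        exhausted=exhausted,
    )
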