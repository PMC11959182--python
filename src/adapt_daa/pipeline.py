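"""The three-stage differential abundance pipeline.

Stage 1 fits a Firth-penalized Tobit model to each taxon's log relative
abundance and pools the condition P-values.  If the pooled P-values are
uniform or left-skewed, no taxon is differentially abundant and the
stage-1 results are reported as final (normalizing by all taxa, i.e. the
library size).  Otherwise stage 2 selects a reference set of presumed
non-DA taxa by iterative halving, and stage 3 refits every taxon against
the log ratio of its counts to the summed reference counts — by the
reference-taxa identity, the condition coefficient of that fit estimates
the log *absolute*-abundance fold change.  Benjamini-Hochberg adjustment
of the stage-3 P-values yields the DA calls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .data_io import (
    CensoredCountTable,
    CountTable,
    CovariateDesign,
    SampleMetadata,
    ValidationError,
    align_metadata,
    censor,
    filter_by_prevalence,
)
from .reference import (
    ReferenceSelection,
    select_reference,
    subset_responses,
)
from .skewness import BumFit, test_right_skew
from .tobit import TobitConfig, TobitFit, fit_all_taxa

__all__ = [
    "AdaptConfig",
    "AdaptResult",
    "stage1_relative_abundance",
    "run_adapt",
    "bh_adjust",
    "write_results",
    "read_results",
]

_LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class AdaptConfig:
    """Tunable thresholds of the pipeline.

    ``alpha`` is the DA-call cutoff on BH-adjusted P-values, ``bum_level``
    the significance level of the beta-uniform-mixture skewness test, and
    ``denominator_mode`` chooses whether normalization denominators sum
    raw counts (``"raw"``, the default: the formulas star only the
    numerator) or censoring proxies (``"starred"``).
    """

    detection_limit: float = 1.0
    prevalence_cutoff: float = 0.05
    alpha: float = 0.05
    bum_level: float = 0.05
    min_reference_size: int | None = None
    denominator_mode: str = "raw"
    seed: int | None = None
    n_jobs: int = 1
    tobit: TobitConfig = field(default_factory=TobitConfig)

    def __post_init__(self) -> None:
        if self.detection_limit <= 0:
            raise ValidationError("detection_limit must be positive")
        for name in ("alpha", "bum_level"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if not 0 <= self.prevalence_cutoff <= 1:
            raise ValidationError("prevalence_cutoff must lie in [0, 1]")
        if self.denominator_mode not in ("raw", "starred"):
            raise ValidationError("denominator_mode must be 'raw' or 'starred'")


@dataclass
class AdaptResult:
    """Per-taxon differential abundance results plus run diagnostics."""

    taxon_ids: list[str]
    log10_fold_change: np.ndarray
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    da_flag: np.ndarray
    reference_taxa: list[str]
    global_null_verdict: bool
    stage1_pvalues: np.ndarray
    selection: ReferenceSelection | None = None
    bum_fit: BumFit | None = None
    stage_fits: list[TobitFit] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)
    config: AdaptConfig | None = None

    @property
    def da_taxa(self) -> list[str]:
        return [t for t, f in zip(self.taxon_ids, self.da_flag) if f]

    def to_dataframe(self) -> pd.DataFrame:
        ref = set(self.reference_taxa)
        return pd.DataFrame(
            {
                "taxon_id": self.taxon_ids,
                "log10_fold_change": self.log10_fold_change,
                "raw_p": self.raw_p,
                "adjusted_p": self.adjusted_p,
                "da_flag": self.da_flag,
                "is_reference": [t in ref for t in self.taxon_ids],
            }
        )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stage1_relative_abundance(
    cct: CensoredCountTable,
    design: CovariateDesign,
    config: AdaptConfig = AdaptConfig(),
) -> tuple[list[TobitFit], np.ndarray]:
    """Fit every taxon's log relative abundance; pool the condition P-values.

    The relative abundance of taxon j in sample i is y*_ij divided by the
    sample's raw library size, so a zero count in a sample with library
    size L is left-censored at d/L.
    """
    all_taxa = np.arange(cct.n_taxa)
    responses = subset_responses(
        cct,
        subset=all_taxa,
        taxa=all_taxa,
        use_proxy_denominator=(config.denominator_mode == "starred"),
    )
    fits = fit_all_taxa(
        cct, design, responses, config=config.tobit, n_jobs=config.n_jobs
    )
    pvals = np.array([f.p_value for f in fits])
    return fits, pvals


def run_adapt(
    ct: CountTable,
    md: SampleMetadata | pd.DataFrame,
    condition: str,
    covariates: tuple[str, ...] = (),
    config: AdaptConfig = AdaptConfig(),
) -> AdaptResult:
    """Run the full three-stage analysis on a count table and metadata."""
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        if config.prevalence_cutoff > 0:
            ct = filter_by_prevalence(ct, config.prevalence_cutoff)
        design = align_metadata(ct, md, condition, covariates)
        cct = censor(ct, config.detection_limit)
        use_proxy = config.denominator_mode == "starred"

        stage1_fits, stage1_pvals = stage1_relative_abundance(cct, design, config)
        bum = test_right_skew(stage1_pvals, level=config.bum_level)

        if not bum.reject_uniform:
            # Global null: normalizing by all taxa equals normalizing by the
            # library size, so the stage-1 fits are the final fits.
            final_fits = stage1_fits
            selection = None
            reference = list(ct.taxon_ids)
            global_null = True
        else:
            selection = select_reference(
                cct,
                design,
                stage1_fits,
                min_size=config.min_reference_size,
                bum_level=config.bum_level,
                config=config.tobit,
                use_proxy_denominator=use_proxy,
                n_jobs=config.n_jobs,
            )
            ref_idx = selection.reference_taxa
            reference = [ct.taxon_ids[i] for i in ref_idx]
            responses = subset_responses(
                cct,
                subset=ref_idx,
                taxa=np.arange(cct.n_taxa),
                use_proxy_denominator=use_proxy,
            )
            final_fits = fit_all_taxa(
                cct, design, responses, config=config.tobit, n_jobs=config.n_jobs
            )
            global_null = False
        captured.extend(str(w.message) for w in wrec)

    raw_p = np.array([f.p_value for f in final_fits])
    adjusted = bh_adjust(raw_p)
    da_flag = adjusted < config.alpha
    log10_fc = np.array([f.tested_estimate for f in final_fits]) / _LN10

    ref_set = set(reference)
    flagged_refs = [
        t for t, f in zip(ct.taxon_ids, da_flag) if f and t in ref_set
    ]
    if flagged_refs and not global_null:
        captured.append(
            f"reference taxa flagged DA (possible contamination): {flagged_refs}"
        )

    nonconv = sum(1 for f in final_fits if not f.converged)
    if nonconv:
        captured.append(f"{nonconv} taxon fit(s) did not fully converge")

    return AdaptResult(
        taxon_ids=list(ct.taxon_ids),
        log10_fold_change=log10_fc,
        raw_p=raw_p,
        adjusted_p=adjusted,
        da_flag=da_flag,
        reference_taxa=reference,
        global_null_verdict=global_null,
        stage1_pvalues=stage1_pvals,
        selection=selection,
        bum_fit=bum,
        stage_fits=final_fits,
        warnings_=captured,
        config=config,
    )


def run_adapt_with_reference(
    ct: CountTable,
    md: SampleMetadata | pd.DataFrame,
    condition: str,
    reference_taxa: list[str],
    covariates: tuple[str, ...] = (),
    config: AdaptConfig = AdaptConfig(),
) -> AdaptResult:
    """Stage-3 analysis with an externally supplied (oracle) reference set.

    Intended for simulation studies where the true non-DA set is known;
    the primary workflow selects its own reference via :func:`run_adapt`.
    """
    if config.prevalence_cutoff > 0:
        ct = filter_by_prevalence(ct, config.prevalence_cutoff)
    design = align_metadata(ct, md, condition, covariates)
    cct = censor(ct, config.detection_limit)
    ref_idx = np.array(
        [i for i, t in enumerate(ct.taxon_ids) if t in set(reference_taxa)], dtype=int
    )
    if ref_idx.size == 0:
        raise ValidationError("no supplied reference taxon is present in the table")
    responses = subset_responses(
        cct,
        subset=ref_idx,
        taxa=np.arange(cct.n_taxa),
        use_proxy_denominator=(config.denominator_mode == "starred"),
    )
    fits = fit_all_taxa(cct, design, responses, config=config.tobit, n_jobs=config.n_jobs)
    raw_p = np.array([f.p_value for f in fits])
    adjusted = bh_adjust(raw_p)
    return AdaptResult(
        taxon_ids=list(ct.taxon_ids),
        log10_fold_change=np.array([f.tested_estimate for f in fits]) / _LN10,
        raw_p=raw_p,
        adjusted_p=adjusted,
        da_flag=adjusted < config.alpha,
        reference_taxa=[ct.taxon_ids[i] for i in ref_idx],
        global_null_verdict=False,
        stage1_pvalues=raw_p,
        stage_fits=fits,
        config=config,
    )


def write_results(res: AdaptResult, path: str | Path) -> None:
    """Write the per-taxon results as TSV with a commented metadata header."""
    path = Path(path)
    cfg = asdict(res.config) if res.config is not None else {}
    cfg.pop("tobit", None)
    header = {
        "version": __version__,
        "global_null_verdict": res.global_null_verdict,
        "n_reference_taxa": len(res.reference_taxa),
        **cfg,
    }
    with open(path, "w") as fh:
        fh.write(f"# adapt_daa results {json.dumps(header, default=str)}\n")
        res.to_dataframe().to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")
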