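"""Sequence-feature annotation and concordance association.

Calls surviving (or failing) the Mendelian filter are annotated with size,
GC content of the reference span, and distances to the nearer chromosome
end (telomere proxy) and to the centromere.  A multivariate logistic
regression of concordance status on the four features, with Bonferroni
correction across them, asks whether discordant calls cluster in particular
sequence contexts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import CallSet, GenomeContext

logger = logging.getLogger(__name__)

FEATURES = ["size_bp", "gc", "dist_telomere", "dist_centromere"]
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class AssociationResult:
    """Per-feature logistic slopes, Wald p-values and significance flags."""

    table: pd.DataFrame  # index: feature; columns: slope, p_value, significant
    alpha: float
    alpha_corrected: float
    converged: bool


def annotate_features(calls: CallSet, context: GenomeContext) -> pd.DataFrame:
    """Feature table for each call: size, GC, telomere and centromere
    distances.

    GC is (G+C)/(A+C+G+T) over the call's reference span, ambiguous bases
    excluded from the denominator; it is NaN (with a logged flag) when no
    sequence is available for the chromosome.  The telomere distance is
    min(start, chrom_length - end); the centromere distance is 0 for calls
    overlapping the centromeric interval, else the gap to its nearer edge
    (NaN when no centromere is defined).
    """
    rows = []
    missing_seq: set[str] = set()
    for c in calls:
        context.check_call(c)
        length = context.chrom_lengths[c.chrom]
        seq = context.sequence.get(c.chrom)
        if seq is None:
            gc = np.nan
            missing_seq.add(c.chrom)
        else:
            span = seq[c.start : c.end]
            acgt = sum(span.count(b) for b in "ACGT")
            gc = (span.count("G") + span.count("C")) / acgt if acgt else np.nan
        cen = context.centromere.get(c.chrom)
        if cen is None:
            dist_cen = np.nan
        else:
            cs, ce = cen
            if c.end > cs and c.start < ce:
                dist_cen = 0
            else:
                dist_cen = cs - c.end if c.end <= cs else c.start - ce
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "status": c.status.value,
                "size_bp": c.size(),
                "gc": gc,
                "dist_telomere": min(c.start, length - c.end),
                "dist_centromere": dist_cen,
            }
        )
    for chrom in sorted(missing_seq):
        logger.warning("no sequence for chromosome %r; gc left missing", chrom)
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "status"] + FEATURES,
    )


def concordance_association(
    rows: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    standardize: bool = True,
    features: list[str] = FEATURES,
) -> AssociationResult:
    """Multivariate logistic regression of ``concordant`` on the features.

    The model is fit by Newton/IRLS (tolerance 1e-8, up to 100 iterations);
    each feature gets a Wald p-value and a significance flag at the
    Bonferroni-corrected level alpha / n_features.  Standardisation (default
    on) rescales the features for numerical stability; it changes the slope
    scale but not the p-values.  Perfect separation is flagged via
    ``converged=False``; a rank-deficient design raises, naming the
    collinear features.
    """
    if "concordant" not in rows.columns:
        raise ValueError("rows must carry a boolean 'concordant' column")
    data = rows.dropna(subset=features + ["concordant"])
    y = data["concordant"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need both concordant and discordant calls to fit")
    if len(data) <= len(features):
        raise ValueError("need more rows than features")
    X = data[features].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        keep_sd = np.where(sd == 0, 1.0, sd)
        X = (X - X.mean(axis=0)) / keep_sd
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = [
            f
            for i, f in enumerate(features)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1)) == rank
        ]
        raise ValueError(f"singular design matrix; collinear features: {collinear}")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(
                method="newton", maxiter=100, tol=1e-8, disp=False
            )
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation and kin
            logger.warning("logistic fit failed to converge: %s", exc)
            nan = float("nan")
            table = pd.DataFrame(
                {"slope": nan, "p_value": nan, "significant": False}, index=features
            )
            return AssociationResult(table, alpha, alpha / len(features), False)
    corrected = alpha / len(features)
    table = pd.DataFrame(
        {
            "slope": fit.params[1:],
            "p_value": fit.pvalues[1:],
            "significant": fit.pvalues[1:] < corrected,
        },
        index=features,
    )
    if not converged:
        table["significant"] = False
    return AssociationResult(table, alpha, corrected, converged)


def label_concordance(
    calls: CallSet, inherited: CallSet
) -> pd.Series:
    """Boolean concordance labels for ``calls``: True when the call is part
    of the Mendelian-consistent (inherited) subset."""
    inherited_keys = {c.key for c in inherited}
    return pd.Series([c.key in inherited_keys for c in calls], name="concordant")
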