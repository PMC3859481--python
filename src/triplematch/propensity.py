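"""Multiple propensity scores via multinomial logistic regression.

For G treatment groups each subject has a vector of G propensity scores
(p_1, ..., p_G) — the probabilities of receiving each treatment
conditional on covariates — which sum to one.  With more than two groups
the component variances differ, so matching and caliper construction work
on all G components rather than a single score: each component is mapped
to the logit scale and a pooled standard deviation is computed per
component across the group samples, using (n_i - 1) weights as in the
classic two-sample pooled SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PROB_CLIP",
    "EstimationError",
    "CaliperSpec",
    "estimate_multinomial_ps",
    "logit_transform",
    "pooled_sd",
    "pooled_sds",
]

#: Probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] before any logit.
PROB_CLIP = 1e-12


class EstimationError(RuntimeError):
    """Propensity model failed to converge or is degenerate."""


def estimate_multinomial_ps(
    table: pd.DataFrame,
    covariate_names: list[str] | tuple[str, ...],
    group_col: str = "group",
) -> np.ndarray:
    """Fit a multinomial logit of group membership on covariates.

    The highest group label is the base (control) category.  Returns an
    (n, G) matrix of predicted probabilities whose columns follow the
    sorted group labels and whose rows sum to one; probabilities are
    clipped away from 0 and 1 so downstream logits stay finite.

    An empty ``covariate_names`` fits the intercept-only model, whose
    fitted probabilities are the group proportions.

    Raises
    ------
    EstimationError
        If the maximum-likelihood fit does not converge (e.g. perfect
        separation of a group by some covariate).
    """
    labels = np.sort(table[group_col].unique())
    counts = table[group_col].value_counts()
    if (counts < 2).any():
        raise EstimationError("every group needs at least 2 subjects")
    missing = [c for c in covariate_names if c not in table.columns]
    if missing:
        raise EstimationError(f"covariates not in table: {missing}")
    if table[list(covariate_names)].isna().any().any():
        raise EstimationError("missing covariate values")

    # Recode so the highest label is category 0 (the reference), the rest
    # keep their order; probabilities are invariant to this choice but the
    # coefficient parameterization matches the control-as-base convention.
    code = {lab: i + 1 for i, lab in enumerate(labels[:-1])}
    code[labels[-1]] = 0
    endog = table[group_col].map(code).to_numpy()
    exog = sm.add_constant(
        table[list(covariate_names)].to_numpy(dtype=float), has_constant="add"
    )
    model = sm.MNLogit(endog, exog)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(method="newton", maxiter=200, disp=0)
    except Exception as exc:  # singular Hessian, overflow, ...
        raise EstimationError(f"multinomial logit fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationError(
            "multinomial logit did not converge "
            "(possible perfect separation of a treatment group)"
        )
    probs = np.asarray(res.predict(exog))
    # Column j of predict() is recoded category j: 0 = base = labels[-1].
    order = np.empty(len(labels), dtype=int)
    for lab, c in code.items():
        order[np.searchsorted(labels, lab)] = c
    probs = probs[:, order]
    probs = np.clip(probs, PROB_CLIP, 1.0 - PROB_CLIP)
    return probs


def logit_transform(ps: np.ndarray) -> np.ndarray:
    """Elementwise log(p / (1 - p)) of a propensity matrix."""
    p = np.clip(np.asarray(ps, dtype=float), PROB_CLIP, 1.0 - PROB_CLIP)
    return np.log(p / (1.0 - p))


def pooled_sd(scores: np.ndarray, groups: np.ndarray, component: int) -> float:
    """Pooled SD of one logit component across the group samples.

    sqrt( sum_i (n_i - 1) S_i^2 / sum_i (n_i - 1) ), where S_i is the
    sample SD (ddof=1) of the component within group i.  Reduces to the
    classic two-sample pooled SD when there are two groups.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    x = scores[:, component] if scores.ndim == 2 else scores
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        xi = x[groups == g]
        if len(xi) < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
        num += (len(xi) - 1) * np.var(xi, ddof=1)
        den += len(xi) - 1
    return float(np.sqrt(num / den))


def pooled_sds(scores: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Pooled SD of every logit component; see :func:`pooled_sd`."""
    scores = np.asarray(scores, dtype=float)
    return np.array([pooled_sd(scores, groups, k) for k in range(scores.shape[1])])


@dataclass(frozen=True)
class CaliperSpec:
    """Caliper width as a multiple of per-component pooled logit SDs.

    ``width_multiplier`` is the grid value w (the study examines
    0.1, ..., 0.8); ``pooled_sds`` holds one pooled SD per logit
    component, so the admissible per-component discrepancy between two
    potential matches is w * pooled_sds[k].
    """

    width_multiplier: float
    pooled_sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.width_multiplier < 0:
            raise ValueError("width_multiplier must be non-negative")
        object.__setattr__(self, "pooled_sds", tuple(float(s) for s in self.pooled_sds))
        if any(s <= 0 for s in self.pooled_sds):
            raise ValueError("pooled SDs must be positive")

    @classmethod
    def from_scores(
        cls,
        scores: np.ndarray,
        groups: np.ndarray,
        width_multiplier: float,
        scale: str = "combined",
    ) -> "CaliperSpec":
        """Build a caliper from logit scores.

        ``scale`` selects the SD the width multiplies: ``"combined"``
        (default) uses the per-component SD over the combined study
        sample; ``"pooled"`` the within-group (n_i - 1)-weighted pooled
        SD.  The combined scale is what reproduces the reference
        simulation study's matching ratios; the pooled scale is the
        classic two-group convention.
        """
        if scale == "combined":
            sds = np.std(np.asarray(scores, dtype=float), axis=0, ddof=1)
        elif scale == "pooled":
            sds = pooled_sds(scores, groups)
        else:
            raise ValueError(f"unknown scale {scale!r}")
        return cls(width_multiplier, tuple(sds))
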