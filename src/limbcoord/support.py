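"""Limb support patterns and their principal axes of variance.

A support pattern is the set of limbs simultaneously in stance. Per
reference-limb stride, the time fraction in each of eight grouped
contact categories is computed (four-limb, three-limb, diagonal pair,
homologous fore/hind pairs, homolateral pair, single limb, no contact);
the raw 16-state fractions are also exposed. Centered PCA then
decomposes the stride-by-category table, and per-PC projections are
regressed on posture covariates with per-mouse structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .strides import StrideSegmentation

LIMB_ORDER = ("left_fore", "right_fore", "left_hind", "right_hind")

SUPPORT_CATEGORIES = (
    "four_limb",
    "three_limb",
    "diagonal",
    "homologous_fore",
    "homologous_hind",
    "homolateral",
    "single_limb",
    "no_contact",
)

__all__ = [
    "LIMB_ORDER",
    "SUPPORT_CATEGORIES",
    "stance_mask",
    "support_fractions",
    "SupportPCA",
    "support_pca",
    "project_and_regress",
]

# 2-limb state -> category (indices into LIMB_ORDER: LF, RF, LH, RH)
_PAIR_CATEGORY = {
    frozenset({0, 3}): "diagonal",  # LF + RH
    frozenset({1, 2}): "diagonal",  # RF + LH
    frozenset({0, 1}): "homologous_fore",
    frozenset({2, 3}): "homologous_hind",
    frozenset({0, 2}): "homolateral",  # LF + LH
    frozenset({1, 3}): "homolateral",  # RF + RH
}


def state_category(state) -> str:
    """Map a 4-bool contact state (LIMB_ORDER) to its grouped category."""
    idx = frozenset(np.flatnonzero(state).tolist())
    n = len(idx)
    if n == 4:
        return "four_limb"
    if n == 3:
        return "three_limb"
    if n == 2:
        return _PAIR_CATEGORY[idx]
    if n == 1:
        return "single_limb"
    return "no_contact"


def stance_mask(segmentations: dict, n_frames: int) -> np.ndarray:
    """Per-frame 4-column boolean contact state from per-limb segmentations.

    A limb is in stance from each stance onset until the next swing
    onset. Frames before the first event take the state implied by the
    first event (in stance if the first event is a swing onset). Raises
    naming the limb when its segmentation is empty.
    """
    mask = np.zeros((n_frames, 4), dtype=bool)
    for j, limb in enumerate(LIMB_ORDER):
        if limb not in segmentations:
            raise ValueError(f"missing segmentation for limb {limb!r}")
        seg: StrideSegmentation = segmentations[limb]
        events = [(int(t), "swing") for t in seg.swing_onsets] + [
            (int(t), "stance") for t in seg.stance_onsets
        ]
        if not events:
            raise ValueError(f"limb {limb!r} has no segmented events")
        events.sort()
        # initial state: in stance iff the first event is a swing onset
        in_stance = events[0][1] == "swing"
        prev = 0
        for t, kind in events:
            mask[prev:t, j] = in_stance
            in_stance = kind == "stance"
            prev = t
        mask[prev:, j] = in_stance
    return mask


def support_fractions(contact: np.ndarray, stride, include_raw: bool = False):
    """Time fraction per grouped support category over one stride.

    ``contact`` is the per-frame state from :func:`stance_mask`;
    ``stride`` is a half-open frame interval. Fractions sum to 1. With
    ``include_raw`` the 16 raw-state fractions (keys ``raw_0`` ...
    ``raw_15``, bit order LF, RF, LH, RH) are included too.
    """
    onset, offset = int(stride[0]), int(stride[1])
    if not (0 <= onset < offset <= contact.shape[0]):
        raise ValueError("stride interval not covered by contact states")
    window = contact[onset:offset]
    d = window.shape[0]
    codes = window @ (1 << np.arange(4))
    fractions = dict.fromkeys(SUPPORT_CATEGORIES, 0.0)
    counts = np.bincount(codes, minlength=16)
    for code in range(16):
        if not counts[code]:
            continue
        state = [(code >> b) & 1 for b in range(4)]
        fractions[state_category(state)] += counts[code] / d
    if include_raw:
        for code in range(16):
            fractions[f"raw_{code}"] = counts[code] / d
    return fractions


@dataclass
class SupportPCA:
    """PCA of per-stride support fractions."""

    loadings: pd.DataFrame  # categories x PCs, orthonormal columns
    variance_explained: np.ndarray  # percent, all PCs
    n_retained: int  # smallest count with cumulative >= threshold
    projections: pd.DataFrame  # strides x PCs
    dropped_columns: list


def support_pca(profiles: pd.DataFrame, cumulative: float = 0.90) -> SupportPCA:
    """Centered PCA of a stride-by-category support-fraction table.

    Fractions share units, so the PCA is on centered, non-standardized
    columns; constant columns are dropped with a note. The sign of each
    PC is fixed by forcing its largest-magnitude loading positive, and
    PCs are retained until cumulative explained variance reaches
    ``cumulative``. Requires at least 10 strides.
    """
    cols = [c for c in SUPPORT_CATEGORIES if c in profiles.columns]
    X = profiles[cols].to_numpy(dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 strides for a support PCA")
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 1e-12]
    dropped = [cols[i] for i in range(X.shape[1]) if i not in keep]
    X = X[:, keep]
    names = [cols[i] for i in keep]
    pca = PCA()
    proj = pca.fit_transform(X)
    load = pca.components_.T  # categories x PCs
    # deterministic sign: largest-|loading| entry positive per PC
    for j in range(load.shape[1]):
        imax = int(np.argmax(np.abs(load[:, j])))
        if load[imax, j] < 0:
            load[:, j] = -load[:, j]
            proj[:, j] = -proj[:, j]
    var_pct = 100.0 * pca.explained_variance_ratio_
    n_keep = int(np.searchsorted(np.cumsum(var_pct), 100.0 * cumulative) + 1)
    n_keep = min(n_keep, load.shape[1])
    pc_names = [f"PC{j + 1}" for j in range(load.shape[1])]
    return SupportPCA(
        loadings=pd.DataFrame(load, index=names, columns=pc_names),
        variance_explained=var_pct,
        n_retained=n_keep,
        projections=pd.DataFrame(proj, index=profiles.index, columns=pc_names),
        dropped_columns=dropped,
    )


def project_and_regress(
    projections: pd.DataFrame,
    covariates: pd.DataFrame,
    groups,
    pcs=None,
):
    """Linear trend of PC projections on covariates with per-group intercepts.

    Fits, per retained PC, a linear mixed model (random intercept per
    group) of the projection on the supplied covariate columns; falls
    back to OLS when only one group is present. Returns a DataFrame with
    one row per (PC, covariate): estimate, t-like statistic, p-value and
    a 95% Wald interval, plus a ``significant`` flag.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    groups = np.asarray(groups)
    pcs = list(projections.columns) if pcs is None else list(pcs)
    cov_names = list(covariates.columns)
    rows = []
    for pc in pcs:
        df = covariates.copy()
        df["_y"] = projections[pc].to_numpy(dtype=float)
        df["_g"] = groups
        if np.ptp(df["_y"]) < 1e-12:
            for name in cov_names:
                rows.append(
                    {"pc": pc, "covariate": name, "estimate": 0.0, "tvalue": 0.0,
                     "pvalue": 1.0, "ci_lo": 0.0, "ci_hi": 0.0, "significant": False}
                )
            continue
        formula = "_y ~ " + " + ".join(cov_names)
        if len(set(groups.tolist())) > 1:
            model = smf.mixedlm(formula, df, groups=df["_g"]).fit(reml=True, method="lbfgs")
            params, bse, pvals = model.fe_params, model.bse_fe, model.pvalues
        else:
            model = smf.ols(formula, df).fit()
            params, bse, pvals = model.params, model.bse, model.pvalues
        for name in cov_names:
            est = float(params[name])
            se = float(bse[name])
            rows.append(
                {
                    "pc": pc,
                    "covariate": name,
                    "estimate": est,
                    "tvalue": est / se if se > 0 else np.inf,
                    "pvalue": float(pvals[name]),
                    "ci_lo": est - 1.96 * se,
                    "ci_hi": est + 1.96 * se,
                    "significant": bool(float(pvals[name]) < 0.05),
                }
            )
    return pd.DataFrame(rows)
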