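"""Differential cluster abundance and subset-level statistics.

Three layers, all operating on per-subject summaries (never per-cell
values, which would pseudo-replicate within-donor cells):

* per-cluster logistic mixed models of cell membership on clinical
  group, with a per-subject random intercept; the group coefficient is
  the log odds ratio of enrichment;
* linear models of per-subject marker expression quantiles on group;
* paired (blood vs. lymph node within donor) and unpaired (between
  group) Student t tests on per-subject frequencies or mean signal
  intensities.

All p-value families are corrected with the Benjamini-Hochberg step-up
procedure at an FDR threshold of 0.05.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import UNASSIGNED, ClusterLabels
from .events import EventTable
from .gating import SubsetAssignment
from .glmm import fit_binomial_glmm

__all__ = [
    "bh_adjust",
    "fit_cluster_glmm",
    "enrichment_scan",
    "default_contrasts",
    "paired_t",
    "unpaired_t",
    "paired_subject_test",
    "unpaired_group_test",
    "differential_scan",
    "marker_quantile_lm",
]

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q(i) = min_{j >= i} p(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# cluster-membership GLMM


def _subject_counts(labels: ClusterLabels, cluster: int, subject_id: np.ndarray,
                    subjects: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (in-cluster, assigned-total) cell counts.

    Unassigned cells count in neither the numerator nor the total.
    """
    lab = labels.labels
    assigned = lab != UNASSIGNED
    y = np.array([np.sum((subject_id == s) & (lab == cluster)) for s in subjects])
    n = np.array([np.sum((subject_id == s) & assigned) for s in subjects])
    return y.astype(float), n.astype(float)


def fit_cluster_glmm(
    labels: ClusterLabels,
    cluster: int,
    subject_id: np.ndarray,
    subject_groups: Mapping,
    reference: str,
) -> pd.DataFrame:
    """Mixed-model enrichment of one cluster: group log odds ratios.

    Fits a logistic GLMM of per-cell cluster membership (aggregated to
    per-subject binomial counts, which is the same likelihood) on group
    indicators versus ``reference``, with a subject random intercept.
    Returns one row per non-reference group with the coefficient
    estimate (log odds ratio), Wald SE and p-value, the random-effect
    SD, and a fit flag (``ok`` / ``separation`` / ``nonconvergence``).
    """
    subjects = list(subject_groups)
    groups = [subject_groups[s] for s in subjects]
    others = [g for g in dict.fromkeys(groups) if g != reference]
    if reference not in groups or not others:
        raise ValueError(f"need the reference group {reference!r} plus >= 1 other group")
    for g in dict.fromkeys(groups):
        if groups.count(g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    y, n = _subject_counts(labels, cluster, subject_id, subjects)
    if y.sum() == 0:
        raise ValueError(f"cluster {cluster} has no member cells")
    X = np.column_stack(
        [np.ones(len(subjects))] + [[1.0 if g == o else 0.0 for g in groups] for o in others]
    )
    fit = fit_binomial_glmm(y, n, X)
    rows = []
    for j, other in enumerate(others, start=1):
        rows.append({
            "cluster": cluster,
            "contrast": f"{other}_vs_{reference}",
            "log_odds_ratio": fit.beta[j],
            "se": fit.se[j],
            "p_value": fit.p_values[j],
            "subject_sd": fit.sigma,
            "flag": fit.flag,
        })
    return pd.DataFrame(rows)


def default_contrasts(groups: Sequence[str]) -> list[tuple[str, str]]:
    """Pairwise (group, reference) contrasts among the clinical groups.

    For the canonical three-group design the acute-treated group is the
    reference of the first two contrasts; otherwise every later group is
    contrasted against every earlier one.
    """
    groups = list(dict.fromkeys(groups))
    if set(groups) == {"controller", "acute", "chronic"}:
        return [("controller", "acute"), ("chronic", "acute"), ("controller", "chronic")]
    return [(b, a) for i, a in enumerate(groups) for b in groups[i + 1:]]


def enrichment_scan(
    labels: ClusterLabels,
    subject_id: np.ndarray,
    subject_groups: Mapping,
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """GLMM enrichment of every retained cluster under every contrast.

    One two-group fit per (cluster, contrast); BH adjustment is applied
    jointly across all resulting p-values and ``significant`` marks
    adjusted p < 0.05. Flagged fits propagate their flag and are
    excluded from the BH family (their p-value is not interpretable).
    """
    if contrasts is None:
        contrasts = default_contrasts(list(subject_groups.values()))
    clusters = sorted(c for c in np.unique(labels.labels) if c != UNASSIGNED)
    if not clusters:
        raise ValueError("no retained clusters to test")
    frames = []
    for cluster in clusters:
        for group, reference in contrasts:
            pair = {s: g for s, g in subject_groups.items() if g in (group, reference)}
            try:
                frames.append(
                    fit_cluster_glmm(labels, cluster, subject_id, pair, reference)
                )
            except ValueError as e:
                logger.warning("cluster %s, %s vs %s: %s", cluster, group, reference, e)
    table = pd.concat(frames, ignore_index=True)
    ok = (table["flag"] == "ok") & table["p_value"].notna()
    adjusted = np.full(len(table), np.nan)
    if ok.any():
        adjusted[ok.to_numpy()] = bh_adjust(table.loc[ok, "p_value"].to_numpy())
    table["adjusted_p"] = adjusted
    table["significant"] = table["adjusted_p"] < FDR_THRESHOLD
    return table


# ---------------------------------------------------------------------------
# t tests on per-subject summaries


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired Student t test on matched per-subject values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 matched pairs of equal length")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("paired t undefined: zero variance of differences")
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def unpaired_t(x, y) -> tuple[float, float]:
    """Two-sided equal-variance two-sample Student t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per arm")
    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        raise ValueError("unpaired t undefined: zero pooled variance")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def paired_subject_test(
    df: pd.DataFrame,
    value_col: str,
    arm_col: str = "compartment",
    arms: tuple[str, str] = ("blood", "LN"),
    exclude_subjects: Sequence = (),
) -> dict:
    """Paired t on per-subject values across two arms (e.g. blood vs LN).

    Subjects missing either arm (or listed in ``exclude_subjects``,
    which is logged) are dropped; arms are matched by subject id.
    """
    if exclude_subjects:
        logger.info("paired test on %s: excluding subjects %s", value_col,
                    list(exclude_subjects))
        df = df[~df["subject_id"].isin(exclude_subjects)]
    wide = df.pivot_table(index="subject_id", columns=arm_col,
                          values=value_col, aggfunc="first")
    wide = wide.reindex(columns=list(arms)).dropna()
    t, p = paired_t(wide[arms[0]].to_numpy(), wide[arms[1]].to_numpy())
    return {"test": "paired t", "t": t, "p_value": p, "n_pairs": len(wide)}


def unpaired_group_test(
    df: pd.DataFrame,
    value_col: str,
    groups: tuple[str, str],
    group_col: str = "group",
    exclude_subjects: Sequence = (),
) -> dict:
    """Unpaired t on per-subject values between two clinical groups."""
    if exclude_subjects:
        logger.info("unpaired test on %s: excluding subjects %s", value_col,
                    list(exclude_subjects))
        df = df[~df["subject_id"].isin(exclude_subjects)]
    x = df.loc[df[group_col] == groups[0], value_col].dropna().to_numpy()
    y = df.loc[df[group_col] == groups[1], value_col].dropna().to_numpy()
    t, p = unpaired_t(x, y)
    return {"test": "unpaired t", "t": t, "p_value": p,
            "n": f"{len(x)}+{len(y)}"}


def differential_scan(named_frames: Mapping[str, pd.DataFrame], value_col: str,
                      mode: str = "paired", **kwargs) -> pd.DataFrame:
    """Run one paired/unpaired test per named per-subject table, then BH.

    ``named_frames`` maps a row label (subset or marker name) to a
    per-subject summary table as produced by ``subset_frequencies`` or
    ``mean_signal_intensity``. Rows whose test is undefined (zero
    variance, missing arm) are kept with a missing p-value.
    """
    rows = []
    for name, df in named_frames.items():
        try:
            if mode == "paired":
                res = paired_subject_test(df, value_col, **kwargs)
            elif mode == "unpaired":
                res = unpaired_group_test(df, value_col, **kwargs)
            else:
                raise ValueError(f"unknown mode {mode!r}")
        except ValueError as e:
            logger.warning("%s: %s", name, e)
            res = {"test": f"{mode} t", "t": np.nan, "p_value": np.nan}
        rows.append({"name": name, **res})
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    adjusted = np.full(len(out), np.nan)
    if ok.any():
        adjusted[ok.to_numpy()] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    out["adjusted_p"] = adjusted
    out["significant"] = out["adjusted_p"] < FDR_THRESHOLD
    return out


# ---------------------------------------------------------------------------
# marker-quantile linear models


def marker_quantile_lm(
    table: EventTable,
    assign: SubsetAssignment,
    gate: str,
    markers: Sequence[str],
    quantile: float = 0.5,
    reference: str | None = None,
) -> pd.DataFrame:
    """OLS of per-subject marker expression quantiles on clinical group.

    For each marker, the ``quantile`` (default: median) of the
    transformed values over the subject's cells in ``gate`` is the
    response; group indicators versus the reference group are the
    regressors. BH adjustment runs across all (marker, group)
    coefficients jointly.
    """
    import statsmodels.api as sm

    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    mask = assign[gate]
    meta = pd.DataFrame({"subject_id": table.subject_id, "group": table.group})
    group_of = meta.drop_duplicates("subject_id").set_index("subject_id")["group"]
    if reference is None:
        reference = group_of.iloc[0]
    rows = []
    for marker in markers:
        x = table.marker_values(marker)
        per_subject = (
            pd.DataFrame({
                "subject_id": table.subject_id[mask],
                "value": x[mask],
            })
            .groupby("subject_id")["value"]
            .quantile(quantile)
        )
        groups = group_of.loc[per_subject.index]
        for g in dict.fromkeys(group_of):
            if g == reference:
                continue
            if (groups == g).sum() < 2 or (groups == reference).sum() < 2:
                raise ValueError(
                    f"gate {gate!r} non-empty for fewer than 2 subjects in "
                    f"group {g!r} or {reference!r}"
                )
        others = [g for g in dict.fromkeys(group_of) if g != reference]
        X = sm.add_constant(
            np.column_stack([(groups == g).astype(float) for g in others])
        )
        fit = sm.OLS(per_subject.to_numpy(), X).fit()
        for j, g in enumerate(others, start=1):
            rows.append({
                "marker": marker,
                "gate": gate,
                "quantile": quantile,
                "group": g,
                "reference": reference,
                "coefficient": fit.params[j],
                "p_value": fit.pvalues[j],
            })
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["adjusted_p"] < FDR_THRESHOLD
    return out
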