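"""Differential-abundance and signature-metabolite calling for replicated
untargeted LC-MS feature tables.

Pipeline order is fixed: internal-standard normalization -> MAD replicate
outlier removal -> replicate aggregation to accession means -> low-abundance
filter -> pairwise one-tailed differential testing with BH correction ->
signature calling.  The statistical unit is the accession (replicates are
collapsed first); a *DAM* for an ordered pair (A, B) is a feature with
BH-adjusted one-tailed p < 0.05 and raw fold change mean_A/mean_B > 2, and a
*signature metabolite* of group g is a DAM of (g, h) for every other group h.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import itertools
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import GroupAssignment, validate_feature_table

log = logging.getLogger(__name__)

MAD_NORMAL_CONSISTENCY = 1.4826


@dataclasses.dataclass
class DamResult:
    """Long-format differential-abundance results.

    ``table`` has one row per (feature, ordered group pair) with columns
    feature, group_a, group_b, n_a, n_b, mean_a, mean_b, fold_change,
    pvalue, padj, is_dam_up.  ``skipped`` lists (feature, group) pairs with
    fewer than two accession values, excluded from testing.
    """

    table: pd.DataFrame
    skipped: pd.DataFrame
    alpha: float
    fc_min: float

    def group_means(self) -> pd.DataFrame:
        """Features x groups matrix of accession-mean abundances."""
        m = self.table.drop_duplicates(["feature", "group_a"])
        return m.pivot(index="feature", columns="group_a", values="mean_a")


@dataclasses.dataclass
class SignatureCall:
    """Per-group signature metabolites with supporting statistics.

    ``members`` maps each group to its (sorted) signature features;
    ``summary`` has one row per signature feature: its group, per-group mean
    abundances, and the minimum fold over the other groups' means.
    """

    members: dict[str, list[str]]
    summary: pd.DataFrame


def normalize_internal_standard(ft: pd.DataFrame, is_feature_id: str) -> pd.DataFrame:
    """Scale each sample column to equalize the internal-standard signal.

    Every column is multiplied by ``median(IS) / IS_column``, so a sample
    whose internal standard read twice the median is halved.  The IS row is
    removed from the output.
    """
    ft = validate_feature_table(ft)
    if is_feature_id not in ft.index:
        raise KeyError(f"internal standard {is_feature_id!r} not in table")
    is_row = ft.loc[is_feature_id]
    bad = is_row.index[(is_row.isna()) | (is_row == 0)].tolist()
    if bad:
        raise ValueError(f"internal standard missing or zero in samples: {bad}")
    factors = is_row.median() / is_row
    out = ft.drop(index=is_feature_id)
    return out * factors


def mad_outlier_filter(ft: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Discard aberrant replicates per (feature, accession) using the MAD rule.

    Within each replicate vector, a value ``x`` is set missing when
    ``|x - median| > k * 1.4826 * MAD``; when MAD is zero (a majority of
    identical replicates) any value differing from the median is discarded.
    Requires at least 3 replicates per accession.
    """
    ft = validate_feature_table(ft)
    ft = ft.sort_index(axis=1)
    accessions = ft.columns.get_level_values(0).unique()
    n_rep = len(ft[accessions[0]].columns)
    if n_rep < 3:
        raise ValueError(f"MAD filter needs >= 3 replicates, got {n_rep}")
    values = ft.to_numpy(dtype=float).reshape(len(ft.index), len(accessions), n_rep)
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(values, axis=2, keepdims=True)
        mad = np.nanmedian(np.abs(values - med), axis=2, keepdims=True)
        dev = np.abs(values - med)
        discard = np.where(
            mad > 0,
            dev > k * MAD_NORMAL_CONSISTENCY * mad,
            dev > 0,
        ) & ~np.isnan(values)
    out = values.copy()
    out[discard] = np.nan
    n_disc = int(discard.sum())
    log.info(
        "mad_outlier_filter: discarded %d of %d replicate values (%.2f%%)",
        n_disc,
        int((~np.isnan(values)).sum()),
        100.0 * n_disc / max(1, (~np.isnan(values)).sum()),
    )
    return pd.DataFrame(
        out.reshape(len(ft.index), -1), index=ft.index, columns=ft.columns
    )


def aggregate_replicates(ft: pd.DataFrame) -> pd.DataFrame:
    """Mean over surviving (non-missing) replicates per (feature, accession)."""
    ft = validate_feature_table(ft)
    return ft.T.groupby(level="accession").mean().T


def low_abundance_filter(profile: pd.DataFrame, min_abundance: float = 500.0) -> pd.DataFrame:
    """Drop features whose abundance stays below ``min_abundance`` everywhere.

    A feature is retained iff its maximum accession-level abundance is at
    least ``min_abundance``.
    """
    keep = profile.max(axis=1, skipna=True) >= min_abundance
    log.info(
        "low_abundance_filter: kept %d of %d features (threshold %g)",
        int(keep.sum()),
        len(keep),
        min_abundance,
    )
    return profile.loc[keep]


def _one_tailed_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> np.ndarray:
    """Row-wise one-tailed p-values for H1: mean(a) > mean(b), NaN-aware.

    Degenerate rows (zero variance in both groups) get p = 0 when the first
    mean is strictly larger and p = 1 otherwise.
    """
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trigger a scipy precision warning; the NaN result
        # is resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            a, b, axis=1, equal_var=equal_var, nan_policy="omit", alternative="greater"
        )
        p = np.asarray(res.pvalue, dtype=float)
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    degenerate = np.isnan(p)
    p[degenerate & (mean_a > mean_b)] = 0.0
    p[degenerate & ~(mean_a > mean_b)] = 1.0
    return p


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def pairwise_dam(
    profile: pd.DataFrame,
    groups: GroupAssignment,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    equal_var: bool = True,
) -> DamResult:
    """Differentially accumulated metabolites for every ordered group pair.

    For each ordered pair (A, B) and feature: pooled-variance Student t on
    accession means (Welch with ``equal_var=False``), one-tailed p for
    H1: mean_A > mean_B, BH correction across features *within* the ordered
    pair, and the DAM flag ``padj < alpha and fold_change > fc_min`` on raw
    means.  Features with fewer than two accession values in a group are
    skipped for pairs involving that group and recorded in ``skipped``.
    """
    labels = groups.labels_for(profile.columns)
    group_cols = {g: profile.columns[labels == g] for g in groups.group_labels}
    for g, cols in group_cols.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 accessions")
    arrays = {g: profile[cols].to_numpy(dtype=float) for g, cols in group_cols.items()}
    counts = {g: (~np.isnan(a)).sum(axis=1) for g, a in arrays.items()}
    with np.errstate(invalid="ignore", divide="ignore"):
        means = {
            g: np.where(counts[g] > 0, np.nansum(a, axis=1) / counts[g], np.nan)
            for g, a in arrays.items()
        }

    skipped_rows = []
    for g in groups.group_labels:
        for f in profile.index[counts[g] < 2]:
            skipped_rows.append((f, g))
    skipped = pd.DataFrame(skipped_rows, columns=["feature", "group"])

    frames = []
    for a, b in itertools.permutations(groups.group_labels, 2):
        testable = (counts[a] >= 2) & (counts[b] >= 2)
        if not testable.any():
            continue
        pa = _one_tailed_t(arrays[a][testable], arrays[b][testable], equal_var)
        padj = bh_adjust(pa)
        mean_a = means[a][testable]
        mean_b = means[b][testable]
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = mean_a / mean_b
        frames.append(
            pd.DataFrame(
                {
                    "feature": profile.index[testable],
                    "group_a": a,
                    "group_b": b,
                    "n_a": counts[a][testable],
                    "n_b": counts[b][testable],
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "fold_change": fc,
                    "pvalue": pa,
                    "padj": padj,
                    "is_dam_up": (padj < alpha) & (fc > fc_min),
                }
            )
        )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "feature", "group_a", "group_b", "n_a", "n_b",
                "mean_a", "mean_b", "fold_change", "pvalue", "padj", "is_dam_up",
            ]
        )
    )
    return DamResult(table=table, skipped=skipped, alpha=alpha, fc_min=fc_min)


def min_fold_ratio(group_means: Mapping[str, float] | pd.Series, focal_group: str) -> float:
    """Focal-group mean divided by the largest non-focal group mean.

    This is the headline "at least x-fold" statistic quoted for signature
    metabolites.  Returns ``inf`` (logged) when every non-focal mean is zero.
    """
    means = pd.Series(group_means, dtype=float)
    if focal_group not in means.index:
        raise KeyError(f"unknown focal group {focal_group!r}")
    if len(means) < 2:
        raise ValueError("need means for at least two groups")
    if (means < 0).any():
        raise ValueError("group means must be non-negative")
    others = means.drop(focal_group)
    top = others.max()
    if top == 0:
        log.info("min_fold_ratio: all non-focal means are zero, ratio=inf")
        return float("inf")
    return float(means[focal_group] / top)


def signature_metabolites(dam: DamResult, groups: GroupAssignment | None = None) -> SignatureCall:
    """Call signature metabolites: up-DAM versus *every* other group.

    A feature belongs to group g iff ``is_dam_up`` holds for (g, h) for all
    h != g.  Mutual exclusivity of "up in g vs h" and "up in h vs g"
    guarantees the per-group sets are pairwise disjoint.  Features missing
    any pairwise test (insufficient coverage) cannot qualify.
    """
    table = dam.table
    group_labels = (
        list(groups.group_labels)
        if groups is not None
        else sorted(set(table["group_a"]) | set(table["group_b"]))
    )
    n_other = len(group_labels) - 1
    members: dict[str, list[str]] = {g: [] for g in group_labels}
    up = table[table["is_dam_up"]]
    for g in group_labels:
        counts = up[up["group_a"] == g].groupby("feature").size()
        members[g] = sorted(counts.index[counts == n_other])

    means = dam.group_means()
    rows = []
    for g in group_labels:
        for feature in members[g]:
            feature_means = means.loc[feature, group_labels]
            rows.append(
                {
                    "feature": feature,
                    "signature_group": g,
                    **{f"mean_{h}": feature_means[h] for h in group_labels},
                    "min_fold_over_others": min_fold_ratio(feature_means, g),
                }
            )
    summary = pd.DataFrame(
        rows,
        columns=["feature", "signature_group"]
        + [f"mean_{h}" for h in group_labels]
        + ["min_fold_over_others"],
    )
    return SignatureCall(members=members, summary=summary)


def run_pipeline(
    ft: pd.DataFrame,
    groups: GroupAssignment,
    is_feature_id: str | None = None,
    mad_k: float = 3.0,
    min_abundance: float = 500.0,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    equal_var: bool = True,
    exclude_features: list[str] | None = None,
) -> tuple[pd.DataFrame, DamResult, SignatureCall]:
    """Run the full metabolomics chain in its fixed order.

    ``exclude_features`` drops known fragment-ion features (curated
    externally) before testing.  Returns the accession profile, the DAM
    table and the signature call.
    """
    if is_feature_id is not None:
        ft = normalize_internal_standard(ft, is_feature_id)
    ft = mad_outlier_filter(ft, k=mad_k)
    profile = aggregate_replicates(ft)
    profile = low_abundance_filter(profile, min_abundance=min_abundance)
    if exclude_features:
        profile = profile.drop(index=[f for f in exclude_features if f in profile.index])
    dam = pairwise_dam(profile, groups, alpha=alpha, fc_min=fc_min, equal_var=equal_var)
    sig = signature_metabolites(dam, groups)
    return profile, dam, sig


def load_reference_signature_means() -> pd.DataFrame:
    """Curated per-group mean abundances for 40 tea signature metabolites.

    A reference table from a published five-group survey of 134 Chinese tea
    accessions: one row per signature metabolite with its calling group,
    tentative identification, class, and the mean relative abundance in each
    of the five groups (group 1 = CSA; groups 2-5 = CSS subpopulations).
    """
    ref = importlib.resources.files("teasig").joinpath(
        "data/signature_metabolite_means.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
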