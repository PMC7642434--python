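"""Windowed nucleotide diversity, Fst, and sweep-region post-processing.

Window presets follow the conventions of transcriptome-scale tea population
scans: Fst on 100-kb sliding windows stepped by 10 kb, nucleotide diversity
on 10-kb windows stepped by 1 kb, and XP-CLR score tracks on non-overlapping
10-kb windows.  Fst uses the Weir & Cockerham (1984) ratio-of-averages
estimator by default (Hudson's estimator is available behind a flag).

The sweep caller consumes an externally produced per-window score track
(e.g. XP-CLR output): the top 5% of windows are merged into candidate
regions, regions are kept if they reach the top-1% window score, and the
survivors are filtered on the ratio of reference-group to focal-group
diversity so that genuinely swept regions (reduced focal diversity, large
ratio) rank in the kept half.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    GT_HET,
    GT_MISSING,
    GenotypeMatrix,
    GroupAssignment,
    SweepRegion,
    validate_window_track,
)

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in base pairs."""

    size_bp: int
    step_bp: int

    def __post_init__(self) -> None:
        if not (self.size_bp >= self.step_bp >= 1):
            raise ValueError("need size_bp >= step_bp >= 1")


#: presets used throughout the analysis
FST_WINDOWS = WindowSpec(100_000, 10_000)
PI_WINDOWS = WindowSpec(10_000, 1_000)
XPCLR_WINDOWS = WindowSpec(10_000, 10_000)


def make_windows(lengths: Mapping[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Enumerate 0-based half-open windows along each scaffold.

    Starts run 0, step, 2*step, ... while start < length; the final window is
    truncated at the scaffold end.
    """
    rows = []
    for scaffold, length in lengths.items():
        if length < 1:
            raise ValueError(f"scaffold {scaffold!r} has length {length}")
        for start in range(0, int(length), spec.step_bp):
            rows.append((scaffold, start, min(start + spec.size_bp, int(length))))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def site_pi(alt_allele_count, called_allele_count):
    """Average pairwise difference at one biallelic site.

    Equals ``2 p (1-p) n / (n-1)`` with ``p`` the alternate-allele frequency
    among ``n`` called alleles — the unbiased per-site heterozygosity.
    Accepts scalars or arrays; NaN where fewer than two alleles were called.
    """
    alt = np.asarray(alt_allele_count, dtype=float)
    n = np.asarray(called_allele_count, dtype=float)
    if np.any(alt > n) or np.any(alt < 0):
        raise ValueError("need 0 <= alt_allele_count <= called_allele_count")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
        pi = np.where(n >= 2, 2.0 * p * (1.0 - p) * n / (n - 1.0), np.nan)
    return float(pi) if pi.ndim == 0 else pi


def _group_site_counts(
    gm: GenotypeMatrix, groups: GroupAssignment, group: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alt alleles, called alleles, het individuals) per site in one group."""
    labels = groups.labels_for(gm.sample_ids)
    sub = gm.calls[labels == group, :]
    if sub.shape[0] == 0:
        raise ValueError(f"group {group!r} has no samples in the matrix")
    called = sub != GT_MISSING
    alt = np.where(called, sub, 0).sum(axis=0)
    het = (sub == GT_HET).sum(axis=0)
    return alt.astype(float), 2.0 * called.sum(axis=0), het.astype(float)


def _window_slices(
    gm: GenotypeMatrix, windows: pd.DataFrame
) -> list[np.ndarray]:
    """Site indices falling inside each window (0-based half-open vs pos-1)."""
    pos0 = gm.positions - 1
    by_scaffold: dict[str, np.ndarray] = {}
    for scaf in pd.unique(gm.scaffolds):
        by_scaffold[scaf] = np.flatnonzero(gm.scaffolds == scaf)
    out = []
    for scaffold, start, end in windows[["scaffold", "start", "end"]].itertuples(index=False):
        idx = by_scaffold.get(scaffold)
        if idx is None:
            out.append(np.empty(0, dtype=np.int64))
            continue
        p = pos0[idx]
        lo = np.searchsorted(p, start, side="left")
        hi = np.searchsorted(p, end, side="left")
        out.append(idx[lo:hi])
    return out


def window_pi(
    gm: GenotypeMatrix,
    groups: GroupAssignment,
    focal_group: str,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Nucleotide diversity per window for one group.

    Per window: sum of per-site pairwise differences over the SNPs inside,
    divided by the window length in bp.  Invariant sites are assumed
    monomorphic, so windows with no called SNPs get pi = 0.
    """
    alt, n_alleles, _ = _group_site_counts(gm, groups, focal_group)
    per_site = site_pi(alt, n_alleles)
    per_site = np.where(np.isnan(per_site), 0.0, per_site)
    values = []
    for (start, end), idx in zip(
        windows[["start", "end"]].itertuples(index=False), _window_slices(gm, windows)
    ):
        values.append(per_site[idx].sum() / (end - start))
    track = windows.copy()
    track["value"] = values
    return validate_window_track(track)


def weir_cockerham_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components for two demes.

    Parameters are per-site arrays stacked over the two populations:
    ``n`` sample sizes (called diploids, shape (2, S)), ``p`` alternate
    allele frequencies, ``h`` observed heterozygote proportions.  Returns
    the (a, b, c) components: among-population, among-individual-within-
    population, and within-individual variance.
    """
    r = 2.0
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    return a, b, c


def hudson_components(
    n: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator/denominator of Hudson's Fst (allele counts in ``n``
    diploids per population)."""
    n_alleles = 2.0 * n
    p1, p2 = p[0], p[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n_alleles[0] - 1.0)
            - p2 * (1 - p2) / (n_alleles[1] - 1.0)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def window_fst(
    gm: GenotypeMatrix,
    groups: GroupAssignment,
    group_a: str,
    group_b: str,
    windows: pd.DataFrame,
    estimator: str = "wc",
) -> pd.DataFrame:
    """Multi-locus Fst per window between two groups.

    The default is the Weir–Cockerham ratio of summed variance components
    ``sum(a) / sum(a+b+c)`` over the SNPs in the window; ``estimator="hudson"``
    switches to Hudson's ratio-of-sums.  Windows with no usable SNPs (a site
    is usable when both groups have at least one called genotype) are NaN.
    """
    if estimator not in ("wc", "hudson"):
        raise ValueError("estimator must be 'wc' or 'hudson'")
    for g in (group_a, group_b):
        if len(groups.members(g)) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples for Fst")
    alt_a, m_a, het_a = _group_site_counts(gm, groups, group_a)
    alt_b, m_b, het_b = _group_site_counts(gm, groups, group_b)
    n = np.vstack([m_a, m_b]) / 2.0  # diploid counts
    usable = (n > 0).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.vstack([alt_a, alt_b]) / (2.0 * n)
        h = np.vstack([het_a, het_b]) / n
    if estimator == "wc":
        num, d1, d2 = weir_cockerham_components(n, p, h)
        den = num + d1 + d2
    else:
        usable = (n > 1).all(axis=0) & usable  # unbiased Hudson needs >=2 alleles
        num, den = hudson_components(n, p)
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    values = []
    for idx in _window_slices(gm, windows):
        idx = idx[usable[idx]] if idx.size else idx
        d = den[idx].sum()
        values.append(num[idx].sum() / d if idx.size and d != 0 else np.nan)
    track = windows.copy()
    track["value"] = values
    return validate_window_track(track)


# ---------------------------------------------------------------------------
# sweep-region post-processing
# ---------------------------------------------------------------------------

def nearest_rank_quantile(values: Sequence[float] | np.ndarray, q: float) -> float:
    """Empirical quantile by the nearest-rank (inverse ECDF) definition."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no values")
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must be in [0, 1]")
    k = max(1, math.ceil(q * v.size))
    return float(v[k - 1])


def _region_pi_mean(track: pd.DataFrame, scaffold: str, start: int, end: int) -> float:
    sel = track[
        (track["scaffold"] == scaffold)
        & (track["start"] < end)
        & (track["end"] > start)
    ]
    if sel.empty:
        raise ValueError(
            f"diversity track has no windows overlapping {scaffold}:{start}-{end}"
        )
    # windows with no SNPs carry pi = 0, not missing, in region-scale means
    return float(np.nan_to_num(sel["value"].to_numpy(), nan=0.0).mean())


def call_sweep_regions(
    score_track: pd.DataFrame,
    pi_focal: pd.DataFrame,
    pi_reference: pd.DataFrame,
    top_window_frac: float = 0.05,
    top_region_frac: float = 0.01,
    pi_ratio_keep_frac: float = 0.50,
) -> list[SweepRegion]:
    """Candidate sweep regions from a per-window score track plus pi filter.

    Steps:

    1. select windows whose score reaches the empirical ``1 - top_window_frac``
       quantile (nearest-rank, ties kept);
    2. merge book-ended/adjacent selected windows on a scaffold into regions,
       scoring each region by its best member window;
    3. keep regions reaching the ``1 - top_region_frac`` quantile of window
       scores;
    4. compute each region's pi ratio = mean reference-group diversity over
       mean focal-group diversity across overlapping windows (swept regions,
       with reduced focal diversity, give large ratios) and keep regions whose
       ratio reaches the ``1 - pi_ratio_keep_frac`` quantile (interpolated)
       of the surviving candidates.

    Zero focal diversity in a region yields an infinite ratio, which is kept
    and logged.  Reported regions never overlap and are sorted by
    (scaffold, start).
    """
    score_track = validate_window_track(score_track)
    pi_focal = validate_window_track(pi_focal)
    pi_reference = validate_window_track(pi_reference)
    scores = score_track["value"].to_numpy()
    finite = scores[~np.isnan(scores)]
    if finite.size == 0:
        raise ValueError("score track has no usable windows")
    t_window = nearest_rank_quantile(finite, 1.0 - top_window_frac)
    t_region = nearest_rank_quantile(finite, 1.0 - top_region_frac)

    selected = score_track[scores >= t_window].sort_values(
        ["scaffold", "start"], kind="stable"
    )
    regions: list[dict] = []
    for row in selected.itertuples(index=False):
        if (
            regions
            and regions[-1]["scaffold"] == row.scaffold
            and row.start <= regions[-1]["end"]
        ):
            regions[-1]["end"] = max(regions[-1]["end"], row.end)
            regions[-1]["score"] = max(regions[-1]["score"], row.value)
            regions[-1]["n"] += 1
        else:
            regions.append(
                {
                    "scaffold": row.scaffold,
                    "start": int(row.start),
                    "end": int(row.end),
                    "score": float(row.value),
                    "n": 1,
                }
            )
    survivors = [r for r in regions if r["score"] >= t_region]
    if not survivors:
        return []

    ratios = []
    for r in survivors:
        focal = _region_pi_mean(pi_focal, r["scaffold"], r["start"], r["end"])
        ref = _region_pi_mean(pi_reference, r["scaffold"], r["start"], r["end"])
        if focal == 0.0:
            log.info(
                "call_sweep_regions: zero focal diversity in %s:%d-%d, ratio=inf",
                r["scaffold"],
                r["start"],
                r["end"],
            )
            ratios.append(np.inf)
        else:
            ratios.append(ref / focal)
    ratios_arr = np.asarray(ratios)
    finite_ratios = ratios_arr[np.isfinite(ratios_arr)]
    if finite_ratios.size == 0:
        t_ratio = -np.inf  # every candidate swept to zero diversity: keep all
    else:
        # infinite ratios sort above any finite threshold, so the quantile can
        # be taken over the finite values with the infinities counted on top
        n_inf = int(np.isinf(ratios_arr).sum())
        all_for_quantile = np.concatenate(
            [finite_ratios, np.full(n_inf, finite_ratios.max())]
        )
        t_ratio = float(np.quantile(all_for_quantile, 1.0 - pi_ratio_keep_frac))
    kept = [
        SweepRegion(
            scaffold=r["scaffold"],
            start=r["start"],
            end=r["end"],
            region_score=r["score"],
            pi_ratio=float(ratio),
            member_window_count=r["n"],
        )
        for r, ratio in zip(survivors, ratios_arr)
        if ratio >= t_ratio
    ]
    kept.sort(key=lambda r: (r.scaffold, r.start))
    log.info(
        "call_sweep_regions: %d selected windows, %d merged regions, "
        "%d past score threshold, %d past pi-ratio filter",
        len(selected),
        len(regions),
        len(survivors),
        len(kept),
    )
    return kept
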