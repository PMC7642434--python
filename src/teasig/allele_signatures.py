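"""Per-group major alleles and signature-SNP statistics.

A *major allele* of a biallelic SNP within one group is the allele whose
frequency among that group's non-missing alleles is at least a threshold
(default 0.75); below the threshold the major allele is undefined.  A
*signature site* for a pair of groups is a site where both groups have a
defined major allele and they differ; a *group-specific site* is one where
the focal group's major allele differs from the (defined) major allele of
every other group.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .tables_io import GT_MISSING, GenotypeMatrix, GroupAssignment

MAJOR_REF = 0
MAJOR_ALT = 1
MAJOR_UNDEFINED = -1


@dataclasses.dataclass
class MajorAlleleTable:
    """Major allele and its frequency per (group, site).

    ``major`` holds codes {0 ref, 1 alt, -1 undefined}; ``frequency`` holds
    the frequency of the more common allele among non-missing alleles in the
    group (NaN when the group has no called alleles at the site).
    """

    group_labels: list[str]
    major: np.ndarray
    frequency: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.major = np.asarray(self.major, dtype=np.int8)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.major.shape != self.frequency.shape:
            raise ValueError("major and frequency shapes differ")
        if self.major.shape[0] != len(self.group_labels):
            raise ValueError("rows must match group_labels")

    @property
    def n_sites(self) -> int:
        return self.major.shape[1]

    def _row(self, group: str) -> int:
        try:
            return self.group_labels.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}") from None


def major_alleles(
    gm: GenotypeMatrix,
    groups: GroupAssignment,
    threshold: float = 0.75,
) -> MajorAlleleTable:
    """Compute the per-group major-allele table.

    Frequencies are computed over non-missing alleles (two per called
    diploid).  For a biallelic site a frequency tie is 0.5/0.5 and can never
    reach a threshold in (0.5, 1], so no tie-breaking is needed.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must be in (0.5, 1]")
    group_idx = groups.group_indices(gm.sample_ids)
    n_groups = groups.n_groups
    major = np.full((n_groups, gm.n_sites), MAJOR_UNDEFINED, dtype=np.int8)
    freq = np.full((n_groups, gm.n_sites), np.nan)
    for g in range(n_groups):
        sub = gm.calls[group_idx == g, :]
        if sub.shape[0] == 0:
            raise ValueError(f"group {groups.group_labels[g]!r} has no samples in the matrix")
        called = sub != GT_MISSING
        n_alleles = 2.0 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = alt / n_alleles
        p_major = np.maximum(p_alt, 1.0 - p_alt)
        freq[g] = np.where(n_alleles > 0, p_major, np.nan)
        has_calls = n_alleles > 0
        major[g, has_calls & (p_alt >= threshold)] = MAJOR_ALT
        major[g, has_calls & (1.0 - p_alt >= threshold)] = MAJOR_REF
    return MajorAlleleTable(
        group_labels=list(groups.group_labels),
        major=major,
        frequency=freq,
        threshold=threshold,
    )


def divergent_site_indices(
    mat: MajorAlleleTable, group_a: str, group_b: str
) -> np.ndarray:
    """Sites where both groups have defined, differing major alleles."""
    a = mat.major[mat._row(group_a)]
    b = mat.major[mat._row(group_b)]
    return np.flatnonzero((a != MAJOR_UNDEFINED) & (b != MAJOR_UNDEFINED) & (a != b))


def count_divergent_sites(mat: MajorAlleleTable, group_a: str, group_b: str) -> int:
    """Number of signature SNP sites between a pair of groups (symmetric)."""
    return int(divergent_site_indices(mat, group_a, group_b).size)


def group_specific_sites(mat: MajorAlleleTable, focal_group: str) -> np.ndarray:
    """Sites where the focal group's major allele differs from all others.

    Requires a defined major allele in the focal group *and* in every other
    group; a single undefined group excludes the site.
    """
    f = mat._row(focal_group)
    focal = mat.major[f]
    others = np.delete(mat.major, f, axis=0)
    ok = (
        (focal != MAJOR_UNDEFINED)
        & (others != MAJOR_UNDEFINED).all(axis=0)
        & (others != focal[None, :]).all(axis=0)
    )
    return np.flatnonzero(ok)


def pairwise_divergence_matrix(mat: MajorAlleleTable) -> pd.DataFrame:
    """Symmetric K x K table of pairwise signature-site counts."""
    labels = mat.group_labels
    out = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            n = count_divergent_sites(mat, a, b)
            out.loc[a, b] = n
            out.loc[b, a] = n
    return out


def site_flags_frame(mat: MajorAlleleTable, gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site export: major allele per group plus group-specific flags."""
    df = gm.sites_frame()
    code = {MAJOR_REF: "ref", MAJOR_ALT: "alt", MAJOR_UNDEFINED: "undefined"}
    for i, g in enumerate(mat.group_labels):
        df[f"major_{g}"] = [code[int(v)] for v in mat.major[i]]
    for g in mat.group_labels:
        flags = np.zeros(mat.n_sites, dtype=bool)
        flags[group_specific_sites(mat, g)] = True
        df[f"specific_{g}"] = flags
    return df
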