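"""Post-calling SNP filters and codon-degeneracy classification.

The quality filters mirror a standard transcriptome-SNP workflow: keep
biallelic sites with minor allele frequency strictly above 0.05, missing
rate strictly below 20%, and thin clustered SNPs so retained sites are more
than 5 bp apart.  Fourfold-degenerate sites (third codon positions where all
four nucleotides encode the same amino acid) are the preferred marker set
for distance/phylogeny work because they evolve nearly free of protein-level
selection.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .tables_io import GT_MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


def _amino_acid(codon: str) -> str:
    """Translate one codon under the standard genetic code; '*' for stop."""
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


def site_qc_stats(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (minor allele frequency, missing rate).

    MAF is computed over non-missing alleles only (2 * called diploids);
    sites with zero called genotypes get MAF 0.
    """
    calls = gm.calls
    called = calls != GT_MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, alt / (2.0 * n_called), 0.0)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    missing_rate = (gm.n_samples - n_called) / gm.n_samples
    return maf, missing_rate


def qc_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.20,
    min_spacing_bp: int = 5,
) -> GenotypeMatrix:
    """Apply MAF, missing-rate and spacing filters; returns a new matrix.

    Comparisons are strict (MAF > maf_min, missing rate < missing_max).  The
    spacing filter is a greedy left-to-right scan within each scaffold over
    the sites that already passed the first two criteria: a site is kept only
    if it lies more than ``min_spacing_bp`` from the previously *kept* site.
    Filtering is order-preserving and idempotent.
    """
    maf, missing_rate = site_qc_stats(gm)
    pass_maf = maf > maf_min
    pass_missing = missing_rate < missing_max
    candidate = pass_maf & pass_missing

    keep = np.zeros(gm.n_sites, dtype=bool)
    last_kept: dict[str, int] = {}
    for j in np.flatnonzero(candidate):
        scaf = gm.scaffolds[j]
        pos = int(gm.positions[j])
        prev = last_kept.get(scaf)
        if prev is None or pos - prev > min_spacing_bp:
            keep[j] = True
            last_kept[scaf] = pos

    log.info(
        "qc_filter: %d sites in; removed %d by MAF<=%g, %d by missing>=%g, "
        "%d by spacing<=%dbp; %d retained",
        gm.n_sites,
        int((~pass_maf).sum()),
        maf_min,
        int((pass_maf & ~pass_missing).sum()),
        missing_max,
        int((candidate & ~keep).sum()),
        min_spacing_bp,
        int(keep.sum()),
    )
    return gm.take(np.flatnonzero(keep))


def classify_degeneracy(
    cds_sequence: str,
    codon_index: int,
    position_in_codon: int,
) -> int | None:
    """Degeneracy class of one position of a coding sequence.

    Returns the fold-degeneracy of the site under the standard genetic code:
    4 iff substituting any of the four nucleotides leaves the amino acid
    unchanged, 3 or 2 for partial degeneracy, and 0 for a non-degenerate
    site (only the observed base encodes this amino acid).  ``None`` marks
    an unclassifiable codon (ambiguity codes).

    ``codon_index`` is 0-based; ``position_in_codon`` is 0, 1 or 2.
    """
    seq = str(cds_sequence).upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if position_in_codon not in (0, 1, 2):
        raise ValueError("position_in_codon must be 0, 1 or 2")
    start = 3 * codon_index
    codon = seq[start : start + 3]
    if len(codon) < 3:
        raise IndexError(f"codon_index {codon_index} out of range")
    if any(b not in _BASES for b in codon):
        return None
    ref_aa = _amino_acid(codon)
    n_synonymous = sum(
        _amino_acid(codon[:position_in_codon] + b + codon[position_in_codon + 1 :]) == ref_aa
        for b in _BASES
    )
    # field convention: a site with a single synonymous state is "0-fold"
    return {1: 0, 2: 2, 3: 3, 4: 4}[n_synonymous]


def select_fourfold_sites(
    gm: GenotypeMatrix,
    degeneracy: Sequence[int | None],
) -> GenotypeMatrix:
    """Keep sites that are fourfold degenerate and have no missing calls.

    ``degeneracy`` gives one entry per site (``None`` for non-coding or
    unclassifiable sites).
    """
    if len(degeneracy) != gm.n_sites:
        raise ValueError(
            f"{len(degeneracy)} degeneracy annotations for {gm.n_sites} sites"
        )
    fourfold = np.array([d == 4 for d in degeneracy], dtype=bool)
    complete = (gm.calls != GT_MISSING).all(axis=0)
    keep = np.flatnonzero(fourfold & complete)
    log.info(
        "select_fourfold_sites: %d of %d sites are 4-fold with complete calls",
        keep.size,
        gm.n_sites,
    )
    return gm.take(keep)
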