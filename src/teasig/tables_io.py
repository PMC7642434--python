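"""Typed containers and readers/writers for every external format the pipeline touches.

Coordinate convention: VCF positions (1-based) are converted exactly once, at
the VCF boundary.  Everything internal — windows, tracks, sweep regions, BED
output — is 0-based, half-open ``[start, end)``.

Genotypes are stored as small integer codes per (sample, site):
``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

WINDOW_TRACK_COLUMNS = ("scaffold", "start", "end", "value")

_REP_COLUMN_RE = re.compile(r"^(?P<accession>.+)\.rep(?P<rep>\d+)$")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for samples x sites.

    Attributes
    ----------
    sample_ids : list of str
    scaffolds, positions, ref, alt : per-site arrays; positions are 1-based
        (VCF convention) and strictly increasing within each scaffold.
    calls : int8 array of shape (n_samples, n_sites) with codes
        {0 hom-ref, 1 het, 2 hom-alt, -1 missing}.
    """

    sample_ids: list[str]
    scaffolds: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_sites = self.positions.shape[0]
        if not (self.scaffolds.shape[0] == self.ref.shape[0] == self.alt.shape[0] == n_sites):
            raise ValueError("per-site arrays have inconsistent lengths")
        if self.calls.shape != (len(self.sample_ids), n_sites):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {n_sites} sites"
            )
        bad = ~np.isin(self.calls, (GT_MISSING, GT_HOM_REF, GT_HET, GT_HOM_ALT))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        for r, a in zip(self.ref, self.alt):
            if len(str(r)) != 1 or len(str(a)) != 1 or r == a:
                raise ValueError(f"site is not a biallelic SNP: ref={r!r} alt={a!r}")
        for scaf in pd.unique(self.scaffolds):
            pos = self.positions[self.scaffolds == scaf]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    def take(self, site_indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to ``site_indices`` (order preserved)."""
        idx = np.asarray(site_indices, dtype=np.int64)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            scaffolds=self.scaffolds[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            calls=self.calls[:, idx],
        )

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": self.scaffolds,
                "pos": self.positions,
                "ref": self.ref,
                "alt": self.alt,
            }
        )


@dataclasses.dataclass
class GroupAssignment:
    """Mapping of sample IDs to one of K named groups.

    ``group_labels`` fixes the group order used by every downstream table.
    """

    assignments: dict[str, str]
    group_labels: list[str] = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.assignments = dict(self.assignments)
        if self.group_labels is None:
            # order of first appearance
            self.group_labels = list(dict.fromkeys(self.assignments.values()))
        self.group_labels = list(self.group_labels)
        if len(self.group_labels) < 2:
            raise ValueError("need at least 2 groups")
        present = set(self.assignments.values())
        for label in self.group_labels:
            if label not in present:
                raise ValueError(f"group {label!r} has no samples")
        unknown = present - set(self.group_labels)
        if unknown:
            raise ValueError(f"samples assigned to unlisted groups: {sorted(unknown)}")

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def members(self, group: str) -> list[str]:
        if group not in self.group_labels:
            raise KeyError(f"unknown group {group!r}")
        return [s for s, g in self.assignments.items() if g == group]

    def labels_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Group label per sample; raises listing any unassigned samples."""
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise KeyError(f"samples without group assignment: {missing}")
        return np.array([self.assignments[s] for s in sample_ids], dtype=object)

    def group_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Integer group index (into group_labels) per sample."""
        labels = self.labels_for(sample_ids)
        lut = {g: i for i, g in enumerate(self.group_labels)}
        return np.array([lut[l] for l in labels], dtype=np.int64)


@dataclasses.dataclass
class SweepRegion:
    """A candidate selective-sweep region (0-based half-open coordinates)."""

    scaffold: str
    start: int
    end: int
    region_score: float
    pi_ratio: float
    member_window_count: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region end {self.end} <= start {self.start}")
        if self.member_window_count < 1:
            raise ValueError("member_window_count must be >= 1")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    multiallelic: str = "skip",
) -> GenotypeMatrix:
    """Read GT fields of a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are used.  ``multiallelic`` controls what
    happens to records with more than one ALT allele: ``"skip"`` drops them
    (count logged), ``"error"`` raises.  Phased separators are accepted
    (``1|1`` == ``1/1``).
    """
    if multiallelic not in ("skip", "error"):
        raise ValueError("multiallelic must be 'skip' or 'error'")
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    header_samples = list(vcf.header.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise KeyError(f"samples not present in VCF header: {missing}")
        samples = list(sample_subset)
        vcf.subset_samples(samples)
    else:
        samples = header_samples

    scaffolds: list[str] = []
    positions: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[list[int]] = []
    n_multi = 0
    n_nonsnp = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            if multiallelic == "error":
                raise VcfParseError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos} (ALT={','.join(alts) or '.'})"
                )
            n_multi += 1
            continue
        if len(rec.ref) != 1 or len(alts[0]) != 1:
            n_nonsnp += 1
            continue
        codes = []
        for s in samples:
            gt = rec.samples[s].get("GT", (None,))
            if gt is None or any(a is None for a in gt):
                codes.append(GT_MISSING)
            else:
                codes.append(int(sum(gt)))
        scaffolds.append(rec.chrom)
        positions.append(rec.pos)
        ref.append(rec.ref)
        alt.append(alts[0])
        rows.append(codes)
    vcf.close()
    if n_multi:
        log.info("read_vcf_genotypes: skipped %d multi-allelic records", n_multi)
    if n_nonsnp:
        log.info("read_vcf_genotypes: skipped %d non-SNP records", n_nonsnp)
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        scaffolds=np.array(scaffolds, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        calls=calls,
    )


def write_vcf_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (uncompressed text)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for scaf in pd.unique(gm.scaffolds):
        length = int(gm.positions[gm.scaffolds == scaf].max()) + 1
        header.contigs.add(str(scaf), length=length)
    for s in gm.sample_ids:
        header.add_sample(s)
    _gt = {GT_HOM_REF: (0, 0), GT_HET: (0, 1), GT_HOM_ALT: (1, 1), GT_MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(gm.n_sites):
            rec = out.new_record(
                contig=str(gm.scaffolds[j]),
                start=int(gm.positions[j]) - 1,
                alleles=(str(gm.ref[j]), str(gm.alt[j])),
            )
            for i, s in enumerate(gm.sample_ids):
                rec.samples[s]["GT"] = _gt[int(gm.calls[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# group assignments
# ---------------------------------------------------------------------------

def read_group_assignment(path: str | Path) -> GroupAssignment:
    """Read a two-column TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"assignment table is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id entries: {dups}")
    return GroupAssignment(dict(zip(df["sample_id"], df["group"])))


def write_group_assignment(ga: GroupAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(ga.assignments), "group": list(ga.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature tables (metabolomics)
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, header_style: str = "auto") -> pd.DataFrame:
    """Read a replicated metabolite feature table.

    Returns a DataFrame indexed by ``feature_id`` with MultiIndex columns
    ``(accession, replicate)``; replicate indices are 1-based integers.

    Two header dialects are accepted: the documented one-row convention
    ``ACCESSION.rep<k>`` and an explicit two-row header (accession row over
    replicate-index row).  Missing cells stay missing (never imputed).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if header_style not in ("auto", "dotted", "two-row"):
        raise ValueError("header_style must be 'auto', 'dotted' or 'two-row'")
    style = header_style
    if style == "auto":
        with open(path) as fh:
            first = fh.readline().rstrip("\n").split(sep)
        style = "dotted" if all(_REP_COLUMN_RE.match(c) for c in first[1:]) else "two-row"
    if style == "dotted":
        df = pd.read_csv(path, sep=sep, index_col=0)
        cols = []
        for c in df.columns:
            m = _REP_COLUMN_RE.match(str(c))
            if not m:
                raise ValueError(
                    f"column {c!r} does not follow the 'ACCESSION.rep<k>' convention"
                )
            cols.append((m["accession"], int(m["rep"])))
        df.columns = pd.MultiIndex.from_tuples(cols, names=("accession", "replicate"))
    else:
        df = pd.read_csv(path, sep=sep, index_col=0, header=[0, 1])
        df.columns = pd.MultiIndex.from_tuples(
            [(a, int(r)) for a, r in df.columns], names=("accession", "replicate")
        )
    df.index.name = "feature_id"
    return validate_feature_table(df)


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the replicate structure and value domain of a feature table."""
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate feature IDs: {dups}")
    if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 2:
        raise ValueError("feature table needs (accession, replicate) columns")
    reps_per_acc = {
        acc: tuple(sorted(df[acc].columns)) for acc in df.columns.get_level_values(0).unique()
    }
    expected = next(iter(reps_per_acc.values()))
    for acc, reps in reps_per_acc.items():
        if reps != expected:
            raise ValueError(
                f"accession {acc!r} has replicates {reps}, expected {expected}"
            )
    values = df.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("feature abundances must be non-negative")
    return df.astype(float)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table using the ``ACCESSION.rep<k>`` header convention."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = df.copy()
    out.columns = [f"{a}.rep{r}" for a, r in df.columns]
    out.index.name = "feature_id"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# window tracks and score files
# ---------------------------------------------------------------------------

def validate_window_track(track: pd.DataFrame) -> pd.DataFrame:
    track = track.loc[:, list(WINDOW_TRACK_COLUMNS)].copy()
    track["start"] = track["start"].astype(np.int64)
    track["end"] = track["end"].astype(np.int64)
    track["value"] = track["value"].astype(float)
    if (track["end"] <= track["start"]).any():
        raise ValueError("window end must be greater than start")
    for scaf, grp in track.groupby("scaffold", sort=False):
        if np.any(np.diff(grp["start"].to_numpy()) < 0):
            raise ValueError(f"windows not sorted by start on {scaf}")
    return track.reset_index(drop=True)


def read_window_track(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    missing = [c for c in WINDOW_TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"window track is missing columns {missing}")
    return validate_window_track(df)


def write_window_track(track: pd.DataFrame, path: str | Path) -> None:
    validate_window_track(track).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_score_file(
    path: str | Path,
    columns: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Read a whitespace-delimited per-window score file (e.g. XP-CLR output).

    ``columns`` maps the track fields to 0-based column positions; the default
    expects ``scaffold start end value`` in the first four columns.
    """
    colmap = {"scaffold": 0, "start": 1, "end": 2, "value": 3}
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    track = pd.DataFrame(
        {field: raw.iloc[:, pos] for field, pos in colmap.items()}
    )
    track["scaffold"] = track["scaffold"].astype(str)
    return validate_window_track(track)


# ---------------------------------------------------------------------------
# sweep regions (BED)
# ---------------------------------------------------------------------------

def write_regions_bed(regions: Sequence[SweepRegion], path: str | Path) -> None:
    """Write regions as BED-like TSV.

    Columns: scaffold, start, end, name, region_score, pi_ratio,
    member_window_count.  No header; empty input yields an empty file.
    """
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            fh.write(
                f"{r.scaffold}\t{r.start}\t{r.end}\tsweep_{i}\t"
                f"{r.region_score:.6g}\t{r.pi_ratio:.6g}\t{r.member_window_count}\n"
            )


def read_regions_bed(path: str | Path) -> list[SweepRegion]:
    regions: list[SweepRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"malformed region line: {line!r}")
            regions.append(
                SweepRegion(
                    scaffold=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    region_score=float(fields[4]),
                    pi_ratio=float(fields[5]),
                    member_window_count=int(fields[6]),
                )
            )
    return regions
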