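"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study conditions of a five-group tea population
survey: 134 accessions split 29/11/32/26/36 across groups, biallelic
genotypes with Balding–Nichols group structure, replicated (R = 5)
log-normal metabolite feature tables with planted group-specific fold
effects, and per-window score tracks with planted high-score runs and
locally reduced focal-group diversity.  Everything is a pure function of the
configuration (seed included).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    GT_MISSING,
    GenotypeMatrix,
    GroupAssignment,
    validate_feature_table,
    validate_window_track,
)

# rng stream tags so the three generators draw independent substreams
_STREAM_GENOTYPES = 1
_STREAM_METABOLITES = 2
_STREAM_TRACKS = 3


@dataclasses.dataclass(frozen=True)
class PlantedRun:
    """A planted sweep signal: a run of windows with boosted score and
    (optionally) reduced focal-group diversity."""

    scaffold: str
    start_window: int
    n_windows: int
    score_factor: float = 10.0
    pi_factor: float = 0.3


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    The defaults are the study conditions the pipeline is meant for: five
    groups of 29/11/32/26/36 accessions, five replicates per accession in
    the metabolite tables, four-fold planted signature effects, 30%
    log-normal replicate noise, and 10-kb score windows.
    """

    seed: int = 0
    group_sizes: Sequence[int] = (29, 11, 32, 26, 36)
    group_labels: Sequence[str] | None = None

    # genotypes
    n_sites: int = 1000
    n_planted_divergent: int = 100
    planted_group: str | None = None  # defaults to the first group
    fst: float = 0.1  # Balding–Nichols divergence parameter F
    missing_rate: float = 0.02
    planted_focal_alt_freq: float = 0.95
    planted_other_alt_freq: float = 0.05
    genotype_scaffold: str = "scaffold_sim1"

    # metabolites
    n_features: int = 400
    n_planted_signatures_per_group: int = 10
    signature_fold: float = 4.0
    replicate_cv: float = 0.3  # log-sd of replicate noise
    accession_cv: float = 0.3  # log-sd of accession-level noise
    n_replicates: int = 5
    outlier_rate: float = 0.0
    outlier_factor: float = 10.0
    internal_standard_id: str = "IS"
    baseline_log10_mean: float = 3.5
    baseline_log10_sd: float = 0.75

    # sweep tracks
    scaffold_lengths: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"scaffold_sim1": 20_000_000}
    )
    window_size: int = 10_000
    score_shape: float = 4.0
    score_scale: float = 1.0
    pi_level: float = 0.003
    pi_log_sd: float = 0.2
    planted_runs: Sequence[PlantedRun] = (PlantedRun("scaffold_sim1", 700, 5),)

    def __post_init__(self) -> None:
        if self.group_labels is None:
            self.group_labels = tuple(f"group{i + 1}" for i in range(len(self.group_sizes)))
        self.group_labels = tuple(self.group_labels)
        if len(self.group_labels) != len(self.group_sizes):
            raise ValueError("group_labels and group_sizes lengths differ")
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("each group needs at least 2 accessions")
        for rate in (self.missing_rate, self.outlier_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.signature_fold <= 1.0:
            raise ValueError("signature_fold must exceed 1")
        if self.planted_group is None:
            self.planted_group = self.group_labels[0]

    @property
    def n_accessions(self) -> int:
        return int(sum(self.group_sizes))

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_accessions)]

    def assignment(self) -> GroupAssignment:
        ids = self.sample_ids()
        mapping = {}
        k = 0
        for label, size in zip(self.group_labels, self.group_sizes):
            for _ in range(size):
                mapping[ids[k]] = label
                k += 1
        return GroupAssignment(mapping, list(self.group_labels))


@dataclasses.dataclass
class GroundTruth:
    """What was planted, for recovery experiments."""

    planted_divergent: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    planted_signatures: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    planted_outliers: list[tuple[str, str, int]] = dataclasses.field(default_factory=list)
    planted_sweeps: list[tuple[str, int, int]] = dataclasses.field(default_factory=list)

    def write(self, directory: str | Path) -> None:
        """Write the truth as separate TSVs (never embedded in data files)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.planted_divergent:
            pd.DataFrame(
                [(g, int(i)) for g, idx in self.planted_divergent.items() for i in idx],
                columns=["group", "site_index"],
            ).to_csv(directory / "truth_divergent_sites.tsv", sep="\t", index=False)
        if self.planted_signatures:
            pd.DataFrame(
                [(g, f) for g, feats in self.planted_signatures.items() for f in feats],
                columns=["group", "feature_id"],
            ).to_csv(directory / "truth_signature_features.tsv", sep="\t", index=False)
        if self.planted_outliers:
            pd.DataFrame(
                self.planted_outliers, columns=["feature_id", "accession", "replicate"]
            ).to_csv(directory / "truth_outliers.tsv", sep="\t", index=False)
        if self.planted_sweeps:
            pd.DataFrame(
                self.planted_sweeps, columns=["scaffold", "start", "end"]
            ).to_csv(directory / "truth_sweep_regions.tsv", sep="\t", index=False)


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GroupAssignment, GroundTruth]:
    """Biallelic genotypes with group structure and planted divergent sites.

    Neutral sites draw an ancestral frequency p ~ Uniform(0.05, 0.95) and
    per-group frequencies from the Balding–Nichols Beta with mean p and
    variance F p (1-p); genotypes are Binomial(2, group frequency) with
    calls masked missing at ``missing_rate``.  Planted sites for the focal
    group fix the alternate-allele frequency at ``planted_focal_alt_freq``
    there and ``planted_other_alt_freq`` elsewhere.
    """
    if config.n_planted_divergent > config.n_sites:
        raise ValueError("more planted sites than total sites")
    rng = np.random.default_rng([config.seed, _STREAM_GENOTYPES])
    ga = config.assignment()
    n_groups = len(config.group_labels)
    n_samples = config.n_accessions
    group_idx = ga.group_indices(config.sample_ids())

    p_anc = rng.uniform(0.05, 0.95, size=config.n_sites)
    f = config.fst
    shape_a = p_anc * (1.0 - f) / f
    shape_b = (1.0 - p_anc) * (1.0 - f) / f
    group_freq = rng.beta(
        shape_a[None, :], shape_b[None, :], size=(n_groups, config.n_sites)
    )

    planted = np.sort(
        rng.choice(config.n_sites, size=config.n_planted_divergent, replace=False)
    )
    focal = config.group_labels.index(config.planted_group)
    group_freq[:, planted] = config.planted_other_alt_freq
    group_freq[focal, planted] = config.planted_focal_alt_freq

    calls = rng.binomial(2, group_freq[group_idx, :]).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = GT_MISSING

    gaps = rng.integers(10, 500, size=config.n_sites)
    positions = np.cumsum(gaps)
    refs = rng.choice(list("ACGT"), size=config.n_sites)
    offsets = rng.integers(1, 4, size=config.n_sites)
    bases = "ACGT"
    alts = np.array([bases[(bases.index(r) + o) % 4] for r, o in zip(refs, offsets)])

    gm = GenotypeMatrix(
        sample_ids=config.sample_ids(),
        scaffolds=np.full(config.n_sites, config.genotype_scaffold, dtype=object),
        positions=positions,
        ref=refs.astype(object),
        alt=alts.astype(object),
        calls=calls,
    )
    truth = GroundTruth(planted_divergent={config.planted_group: planted})
    return gm, ga, truth


def _feature_ids(rng: np.random.Generator, n: int) -> list[str]:
    """Unique "RT_mz" identifiers (retention-time minutes _ m/z)."""
    ids: list[str] = []
    seen = set()
    while len(ids) < n:
        rt = rng.uniform(1.0, 17.0)
        mz = rng.uniform(100.0, 1200.0)
        fid = f"{rt:.2f}_{mz:.4f}"
        if fid not in seen:
            seen.add(fid)
            ids.append(fid)
    return ids


def simulate_metabolites(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroupAssignment, GroundTruth]:
    """Replicated feature table with planted group-specific fold effects.

    Baselines are log-normal (log10 mean 3.5, sd 0.75, spanning roughly
    1e2-1e5); an accession's level is baseline x group effect x log-normal
    accession noise, and each replicate multiplies in log-normal noise of
    log-sd ``replicate_cv``.  Outliers (at ``outlier_rate``) multiply a
    single replicate by ``outlier_factor``.  An internal-standard row with
    mild (5%) per-sample variation is included.
    """
    n_planted_total = config.n_planted_signatures_per_group * len(config.group_labels)
    if n_planted_total > config.n_features:
        raise ValueError("more planted signature features than total features")
    rng = np.random.default_rng([config.seed, _STREAM_METABOLITES])
    ga = config.assignment()
    ids = config.sample_ids()
    group_idx = ga.group_indices(ids)
    n_groups = len(config.group_labels)

    feature_ids = _feature_ids(rng, config.n_features)
    planted_order = rng.permutation(config.n_features)[:n_planted_total]
    planted_by_group: dict[str, list[str]] = {}
    effect = np.ones((config.n_features, n_groups))
    for gi, g in enumerate(config.group_labels):
        sel = planted_order[
            gi * config.n_planted_signatures_per_group : (gi + 1) * config.n_planted_signatures_per_group
        ]
        effect[sel, gi] = config.signature_fold
        planted_by_group[g] = sorted(feature_ids[i] for i in sel)

    baseline = 10.0 ** rng.normal(
        config.baseline_log10_mean, config.baseline_log10_sd, size=config.n_features
    )
    accession_level = (
        baseline[:, None]
        * effect[:, group_idx]
        * np.exp(rng.normal(0.0, config.accession_cv, size=(config.n_features, len(ids))))
    )
    reps = np.exp(
        rng.normal(
            0.0,
            config.replicate_cv,
            size=(config.n_features, len(ids), config.n_replicates),
        )
    )
    values = accession_level[:, :, None] * reps

    outliers: list[tuple[str, str, int]] = []
    if config.outlier_rate > 0:
        mask = rng.random(values.shape) < config.outlier_rate
        values = np.where(mask, values * config.outlier_factor, values)
        for fi, ai, ri in zip(*np.nonzero(mask)):
            outliers.append((feature_ids[fi], ids[ai], int(ri) + 1))

    is_values = 1.0e4 * np.exp(
        rng.normal(0.0, 0.05, size=len(ids) * config.n_replicates)
    )
    columns = pd.MultiIndex.from_product(
        [ids, range(1, config.n_replicates + 1)], names=("accession", "replicate")
    )
    data = np.vstack([values.reshape(config.n_features, -1), is_values[None, :]])
    ft = pd.DataFrame(data, index=feature_ids + [config.internal_standard_id], columns=columns)
    ft.index.name = "feature_id"
    truth = GroundTruth(planted_signatures=planted_by_group, planted_outliers=outliers)
    return validate_feature_table(ft), ga, truth


def simulate_sweep_tracks(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Score track plus focal/reference diversity tracks with planted runs.

    Background scores are Gamma(shape, scale); both diversity tracks are
    log-normal around ``pi_level``.  Each planted run multiplies the scores
    in its span by ``score_factor`` and the focal-group diversity by
    ``pi_factor``; the reference track is unperturbed.
    """
    rng = np.random.default_rng([config.seed, _STREAM_TRACKS])
    rows = []
    for scaffold, length in config.scaffold_lengths.items():
        for start in range(0, int(length), config.window_size):
            rows.append((scaffold, start, min(start + config.window_size, int(length))))
    windows = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    n = len(windows)
    scores = rng.gamma(config.score_shape, config.score_scale, size=n)
    pi_focal = config.pi_level * np.exp(rng.normal(0.0, config.pi_log_sd, size=n))
    pi_ref = config.pi_level * np.exp(rng.normal(0.0, config.pi_log_sd, size=n))

    offsets = {}
    offset = 0
    for scaffold, length in config.scaffold_lengths.items():
        offsets[scaffold] = offset
        offset += -(-int(length) // config.window_size)

    claimed: set[tuple[str, int]] = set()
    truth_regions = []
    for run in config.planted_runs:
        if run.scaffold not in offsets:
            raise ValueError(f"planted run on unknown scaffold {run.scaffold!r}")
        span = [(run.scaffold, w) for w in range(run.start_window, run.start_window + run.n_windows)]
        if claimed & set(span):
            raise ValueError("planted runs overlap")
        claimed.update(span)
        lo = offsets[run.scaffold] + run.start_window
        hi = lo + run.n_windows
        if hi > n or windows.iloc[hi - 1]["scaffold"] != run.scaffold:
            raise ValueError("planted run extends past its scaffold")
        scores[lo:hi] *= run.score_factor
        pi_focal[lo:hi] *= run.pi_factor
        truth_regions.append(
            (run.scaffold, int(windows.iloc[lo]["start"]), int(windows.iloc[hi - 1]["end"]))
        )

    def _track(values: np.ndarray) -> pd.DataFrame:
        t = windows.copy()
        t["value"] = values
        return validate_window_track(t)

    truth = GroundTruth(planted_sweeps=truth_regions)
    return _track(scores), _track(pi_focal), _track(pi_ref), truth
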