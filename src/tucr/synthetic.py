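"""Synthetic spot-level datasets with the structure of a strand-specific UCR array.

The emulated platform carries a sense ("plus") and an antisense ("minus")
40-mer probe for each of 481 UCRs — 962 probes — each spotted in
quadruplicate (duplicate spots in two slide locations).  Samples are
partitioned into tissue/system groups (16 systems by default).

Generative model (all signal on the log2 scale, multiplicative on the
linear scale):

* every plus probe is "expressed" in a random subset of systems covering
  25–75% of the groups, at ``baseline_log2`` there and at the unexpressed
  background elsewhere — real T-UCRs are tissue-restricted, and a probe
  flat across every sample would carry no fold-change signal;
* minus probes sit at the unexpressed background, except for UCRs planted
  as bidirectional, whose minus probe mirrors the plus probe's pattern;
* planted group-selective probes are expressed *only* in their target
  group, at ``baseline_log2 + effect_log2`` — the single-group pattern that
  makes a probe maximally tissue-selective (IC = log2 n_groups);
* every spot intensity is multiplied by log-normal noise
  ``2**N(0, noise_sd_log2)``; with probability ``absent_rate`` a spot is
  instead replaced by a value below the detection floor (an absent call);
* an optional slide-location offset separates replicate pairs 1–2 and 3–4.

Identical seeds give bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GENOMIC_CLASSES, AnnotationTracks, GenomicInterval, UCRCatalog, write_bed

__all__ = [
    "SYSTEM_NAMES",
    "SyntheticConfig",
    "generate_ucr_catalog",
    "generate_dataset",
    "generate_annotation_tracks",
    "probe_id",
    "split_probe_id",
    "write_dataset",
]

#: Default histological-system labels for the 16-group design.
SYSTEM_NAMES = (
    "epidermis",
    "cns",
    "respiratory",
    "gastrointestinal",
    "liver",
    "placenta",
    "adipose",
    "muscle",
    "cardiovascular",
    "hematologic",
    "immune",
    "urinary",
    "reproductive",
    "endocrine",
    "embryo",
    "sensory",
)

STRANDS = ("plus", "minus")


def probe_id(ucr_id: str, strand: str) -> str:
    """Probe naming convention: ``uc.283`` + ``plus`` → ``uc.283-plus``."""
    if strand not in STRANDS:
        raise ValueError(f"strand must be one of {STRANDS}, got {strand!r}")
    return f"{ucr_id}-{strand}"


def split_probe_id(pid: str) -> tuple[str, str]:
    """Inverse of :func:`probe_id`; raises on ids that do not parse."""
    ucr, sep, strand = pid.rpartition("-")
    if not sep or strand not in STRANDS or not ucr:
        raise ValueError(f"probe id {pid!r} does not parse into (ucr_id, strand)")
    return ucr, strand


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic UCR-array experiment.

    Defaults mirror the emulated study design: 481 UCRs x 2 strands probed in
    quadruplicate over 16 histological systems.  Intensities are linear-scale;
    ``baseline_log2 = 8`` (linear 256) is a typical mid-range spot intensity,
    ``unexpressed_linear = 4`` sits well below the ``detection_floor`` of 32
    so unexpressed probes fail the present call even with noise.
    """

    n_ucrs: int = 481
    n_groups: int = 16
    samples_per_group: int = 4
    n_replicates: int = 4
    baseline_log2: float = 8.0
    effect_log2: float = 3.0
    noise_sd_log2: float = 0.5
    absent_rate: float = 0.02
    unexpressed_linear: float = 4.0
    detection_floor: float = 32.0
    expressed_group_frac: tuple[float, float] = (0.25, 0.75)
    batch_offset_log2: float = 0.0
    planted_selective: list[tuple[str, str]] = field(default_factory=list)
    planted_bidirectional: list[str] = field(default_factory=list)
    class_probs: tuple[float, float, float] = (0.26, 0.26, 0.48)  # exonic, putative, non-exonic
    tissues_per_group: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_ucrs", "n_groups", "samples_per_group", "n_replicates", "tissues_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.absent_rate <= 1.0:
            raise ValueError(f"absent_rate must lie in [0, 1], got {self.absent_rate}")
        if self.noise_sd_log2 < 0:
            raise ValueError(f"noise_sd_log2 must be >= 0, got {self.noise_sd_log2}")
        if self.unexpressed_linear < 0:
            raise ValueError(f"unexpressed_linear must be >= 0, got {self.unexpressed_linear}")
        if self.detection_floor <= 0:
            raise ValueError(f"detection_floor must be > 0, got {self.detection_floor}")
        lo, hi = self.expressed_group_frac
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError(f"expressed_group_frac must satisfy 0 < lo <= hi <= 1, got {self.expressed_group_frac}")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or min(self.class_probs) < 0:
            raise ValueError(f"class_probs must be a probability vector, got {self.class_probs}")
        groups = set(self.group_names())
        ucrs = set(self.ucr_ids())
        probes = {probe_id(u, s) for u in ucrs for s in STRANDS}
        for pid, grp in self.planted_selective:
            if pid not in probes:
                raise ValueError(f"planted_selective probe {pid!r} not on the array")
            if grp not in groups:
                raise ValueError(f"planted_selective group {grp!r} is not a sample group")
        for uid in self.planted_bidirectional:
            if uid not in ucrs:
                raise ValueError(f"planted_bidirectional UCR {uid!r} not in the catalog")

    def ucr_ids(self) -> list[str]:
        return [f"uc.{i}" for i in range(1, self.n_ucrs + 1)]

    def group_names(self) -> list[str]:
        base = list(SYSTEM_NAMES)
        if self.n_groups <= len(base):
            return base[: self.n_groups]
        return base + [f"system{i}" for i in range(len(base) + 1, self.n_groups + 1)]


def generate_ucr_catalog(
    n: int,
    seed: int,
    class_probs: tuple[float, float, float] = (0.26, 0.26, 0.48),
) -> UCRCatalog:
    """Non-overlapping UCR loci with lengths >= 200 nt and sampled context classes.

    ``class_probs`` orders (exonic, putative_exonic, non_exonic); the default
    48% non-exonic / 26% putative exonic / 26% exonic split matches the
    proportions reported for expressed UCRs.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(200, 780, size=n)
    gaps = rng.integers(10_000, 100_000, size=n)
    classes = rng.choice(
        ["exonic", "putative_exonic", "non_exonic"], size=n, p=list(class_probs)
    )
    chroms = [f"chr{1 + i % 22}" for i in range(n)]
    cursor = {c: 1 for c in set(chroms)}
    starts = np.empty(n, dtype=int)
    for i, c in enumerate(chroms):
        starts[i] = cursor[c] + int(gaps[i])
        cursor[c] = starts[i] + int(lengths[i])  # next start > this end
    ends = starts + lengths - 1
    rec = pd.DataFrame(
        {
            "ucr_id": [f"uc.{i}" for i in range(1, n + 1)],
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "genomic_class": classes,
        }
    )
    return UCRCatalog(rec)


def generate_annotation_tracks(catalog: UCRCatalog, seed: int = 0) -> AnnotationTracks:
    """Exon/EST tracks consistent with the catalog's genomic classes.

    Exonic UCRs receive a confirmed exon inside their span (plus, for half of
    them, an EST as well — exon evidence must take precedence); putative-exonic
    UCRs receive only an EST; non-exonic UCRs receive nothing.  Because catalog
    intervals never overlap, evidence placed inside one UCR cannot leak onto a
    neighbour.
    """
    rng = np.random.default_rng(seed)
    exons: list[GenomicInterval] = []
    ests: list[GenomicInterval] = []
    for iv in catalog.intervals():
        cls = catalog.records.loc[catalog.records["ucr_id"] == iv.name, "genomic_class"].iloc[0]
        if cls == "non_exonic":
            continue
        span = iv.end - iv.start
        a = int(rng.integers(0, max(1, span // 2)))
        b = int(rng.integers(a, span + 1))
        sub = GenomicInterval(iv.chrom, iv.start + a, iv.start + b, f"{iv.name}_ev")
        if cls == "exonic":
            exons.append(sub)
            if rng.random() < 0.5:
                ests.append(GenomicInterval(iv.chrom, iv.start, iv.end, f"{iv.name}_est"))
        else:  # putative_exonic
            ests.append(sub)
    return AnnotationTracks(exons=exons, ests=ests)


def _expression_design(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Per-(probe, group) linear-scale expected intensity.

    Returns the probe-id list (plus probes first per UCR) and an
    (n_probes, n_groups) array of linear means.
    """
    groups = cfg.group_names()
    g = cfg.n_groups
    ucrs = cfg.ucr_ids()
    pids: list[str] = []
    base_lin = 2.0 ** cfg.baseline_log2
    sel_lin = 2.0 ** (cfg.baseline_log2 + cfg.effect_log2)
    lo = math.ceil(cfg.expressed_group_frac[0] * g)
    hi = max(lo, math.floor(cfg.expressed_group_frac[1] * g))
    bidir = set(cfg.planted_bidirectional)

    design = np.empty((2 * cfg.n_ucrs, g), dtype=float)
    for i, uid in enumerate(ucrs):
        n_on = int(rng.integers(lo, hi + 1))
        on = rng.choice(g, size=n_on, replace=False)
        plus = np.full(g, cfg.unexpressed_linear)
        plus[on] = base_lin
        minus = plus.copy() if uid in bidir else np.full(g, cfg.unexpressed_linear)
        design[2 * i] = plus
        design[2 * i + 1] = minus
        pids.append(probe_id(uid, "plus"))
        pids.append(probe_id(uid, "minus"))

    gindex = {name: j for j, name in enumerate(groups)}
    pindex = {pid: i for i, pid in enumerate(pids)}
    for pid, grp in cfg.planted_selective:
        row = np.full(g, cfg.unexpressed_linear)
        row[gindex[grp]] = sel_lin
        design[pindex[pid]] = row
    return pids, design


def generate_dataset(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, UCRCatalog]:
    """Generate (SpotTable, SampleAnnotation, UCRCatalog) for one experiment.

    The SpotTable has one row per (probe, sample, replicate) with columns
    ``ucr_id, strand, sample_id, replicate, intensity, flag``; intensities are
    linear-scale and nonnegative, flag 0 means a good spot.  The annotation
    maps each sample to a tissue, a system group and a balanced two-level
    class label (alternating within each group, so the classes are
    exchangeable under the null).
    """
    cfg.validate()
    catalog = generate_ucr_catalog(cfg.n_ucrs, cfg.seed, cfg.class_probs)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    groups = cfg.group_names()
    pids, design = _expression_design(cfg, rng)
    n_probes = len(pids)

    sample_ids: list[str] = []
    ann_rows = []
    for gi, grp in enumerate(groups):
        for j in range(cfg.samples_per_group):
            sid = f"{grp}_s{j + 1:02d}"
            sample_ids.append(sid)
            ann_rows.append(
                {
                    "sample_id": sid,
                    "tissue": f"{grp}_t{1 + j % cfg.tissues_per_group}",
                    "system_group": grp,
                    "class": "A" if j % 2 == 0 else "B",
                }
            )
    annotation = pd.DataFrame(ann_rows)
    n_samples = len(sample_ids)

    # expected linear intensity per (probe, sample)
    sample_group_idx = np.repeat(np.arange(cfg.n_groups), cfg.samples_per_group)
    mu = design[:, sample_group_idx]  # (n_probes, n_samples)

    shape = (n_probes, n_samples, cfg.n_replicates)
    if cfg.noise_sd_log2 > 0:
        noise = 2.0 ** rng.normal(0.0, cfg.noise_sd_log2, size=shape)
    else:
        noise = np.ones(shape)
    intensity = mu[:, :, None] * noise
    if cfg.batch_offset_log2 != 0.0:
        # replicates 1-2 and 3-4 emulate the two slide locations
        half = cfg.n_replicates // 2
        intensity[:, :, half:] *= 2.0 ** cfg.batch_offset_log2

    if cfg.absent_rate > 0:
        absent = rng.random(shape) < cfg.absent_rate
        low = rng.uniform(0.0, 0.5 * cfg.detection_floor, size=shape)
        intensity = np.where(absent, low, intensity)

    ucr_col = np.repeat([split_probe_id(p)[0] for p in pids], n_samples * cfg.n_replicates)
    strand_col = np.repeat([split_probe_id(p)[1] for p in pids], n_samples * cfg.n_replicates)
    sample_col = np.tile(np.repeat(sample_ids, cfg.n_replicates), n_probes)
    rep_col = np.tile(np.arange(1, cfg.n_replicates + 1), n_probes * n_samples)
    spots = pd.DataFrame(
        {
            "ucr_id": ucr_col,
            "strand": strand_col,
            "sample_id": sample_col,
            "replicate": rep_col,
            "intensity": intensity.ravel(),
            "flag": 0,
        }
    )
    return spots, annotation, catalog


def write_dataset(
    spots: pd.DataFrame,
    annotation: pd.DataFrame,
    catalog: UCRCatalog,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three tables (TSV + BED) under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spots": outdir / "spots.tsv",
        "samples": outdir / "samples.tsv",
        "catalog": outdir / "ucr_catalog.bed",
    }
    spots.to_csv(paths["spots"], sep="\t", index=False)
    annotation.to_csv(paths["samples"], sep="\t", index=False)
    write_bed(catalog, paths["catalog"])
    return paths
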