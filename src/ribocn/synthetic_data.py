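"""Synthetic fixtures with known ground truth for every pipeline stage.

The read simulator emulates the sampling structure the proxy estimator assumes:
each read falls in the rDNA compartment with probability
``true_cn * L / (true_cn * L + G)`` (L = toy 18S span, G = numbered-chromosome
background span) and lands uniformly within an 18S-analogue region, otherwise
uniformly on the numbered background contigs. Analogue regions live on an
unplaced scaffold-style contig, as most real 18S analogues do, so the
numbered-chromosome baseline counts exactly the background compartment and
E[region / background] = true_cn * L / G. Placement-only simulation: records
carry no realistic base calls because the estimator consumes placements, not
sequences.

Cohort simulation draws a true copy number per participant (family blocks share
a latent component giving a chosen intra-family correlation), converts it to an
observed ratio with center offsets and measurement noise, and generates traits
with known standardized linear effects or logistic log-odds. Kinship tables are
generated with kinship/IBS0/birth-year values consistent with the relationship
bands. Every generator is deterministic given its seed and returns a truth
table alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ribocn.cn_estimation import (
    ConversionConstants,
    DepthPair,
)
from ribocn.errors import ConfigurationError, ValidationError
from ribocn.reference_prep import AnalogueRegionSet, GenomicInterval
from ribocn.relatedness import KinshipPair

_BASES = np.array(list("ACGT"))


@dataclass
class ReadSimConfig:
    """Geometry and sampling parameters of the toy read simulator."""

    background_genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    analogue_contig: str = "chrUn_rdna_toy"
    analogue_region_length: int = 1_000
    n_analogue_regions: int = 2
    true_cn: float = 300.0
    read_length: int = 100
    n_reads: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ConfigurationError("n_reads must be positive")
        if self.true_cn < 0:
            raise ConfigurationError("true_cn must be non-negative")
        if any(l < self.read_length for l in self.background_genome.values()):
            raise ConfigurationError("background contig shorter than read length")
        for contig in self.background_genome:
            if contig == self.analogue_contig:
                raise ConfigurationError("analogue contig collides with a background contig")

    @property
    def toy_subunit_length(self) -> int:
        """L_toy: total analogue bases, standing in for the 18S subunit span."""
        return self.analogue_region_length * self.n_analogue_regions

    @property
    def background_bases(self) -> int:
        """G_toy: numbered-chromosome background span."""
        return sum(self.background_genome.values())

    @property
    def rdna_read_probability(self) -> float:
        """Per-read probability of the rDNA compartment."""
        cl = self.true_cn * self.toy_subunit_length
        return cl / (cl + self.background_bases)

    @property
    def constants(self) -> ConversionConstants:
        """Conversion constants matching the toy geometry."""
        return ConversionConstants(self.background_bases, self.toy_subunit_length)

    def regions(self) -> AnalogueRegionSet:
        """Analogue intervals laid head-to-tail with 1 kb spacers on the scaffold contig."""
        spacer = 1_000
        intervals = []
        pos = spacer
        for _ in range(self.n_analogue_regions):
            intervals.append(
                GenomicInterval(self.analogue_contig, pos, pos + self.analogue_region_length)
            )
            pos += self.analogue_region_length + spacer
        return AnalogueRegionSet(intervals, query_length=self.toy_subunit_length,
                                 provenance="synthetic")

    @property
    def analogue_contig_length(self) -> int:
        return self.n_analogue_regions * (self.analogue_region_length + 1_000) + 1_000


def simulate_reference(config: ReadSimConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the toy reference FASTA and matching analogue BED; returns their paths."""
    from ribocn.reference_prep import write_region_bed

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    fasta = out_dir / "toy_reference.fa"
    with open(fasta, "w") as fh:
        for contig, length in config.background_genome.items():
            seq = "".join(rng.choice(_BASES, size=length))
            fh.write(f">{contig}\n")
            for i in range(0, length, 80):
                fh.write(seq[i : i + 80] + "\n")
        length = config.analogue_contig_length
        seq = "".join(rng.choice(_BASES, size=length))
        fh.write(f">{config.analogue_contig}\n")
        for i in range(0, length, 80):
            fh.write(seq[i : i + 80] + "\n")
    bed = out_dir / "toy_regions.bed"
    write_region_bed(config.regions(), bed)
    return fasta, bed


def simulate_alignment(config: ReadSimConfig, out_bam: str | Path) -> Path:
    """Write a coordinate-sorted, indexed BAM of placement-only reads.

    Each read joins the rDNA compartment with the compartment probability and
    is placed uniformly within an analogue region; background reads are placed
    uniformly across the numbered contigs (length-weighted).
    """
    out_bam = Path(out_bam)
    out_bam.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    contigs = list(config.background_genome.items()) + [
        (config.analogue_contig, config.analogue_contig_length)
    ]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs],
    }
    tid = {name: i for i, (name, _) in enumerate(contigs)}

    n_rdna = rng.binomial(config.n_reads, config.rdna_read_probability)
    n_bg = config.n_reads - n_rdna

    placements: list[tuple[int, int]] = []
    regions = config.regions().intervals
    region_lengths = np.array([len(iv) for iv in regions])
    if n_rdna and config.true_cn > 0:
        region_idx = rng.choice(len(regions), size=n_rdna, p=region_lengths / region_lengths.sum())
        offsets = rng.integers(0, region_lengths[region_idx] - 1, size=n_rdna)
        rdna_tid = tid[config.analogue_contig]
        for ri, off in zip(region_idx, offsets):
            placements.append((rdna_tid, regions[ri].start + int(off)))
    bg_names = list(config.background_genome)
    bg_lengths = np.array([config.background_genome[c] for c in bg_names], dtype=float)
    bg_choice = rng.choice(len(bg_names), size=n_bg, p=bg_lengths / bg_lengths.sum())
    bg_pos = rng.integers(0, (bg_lengths[bg_choice] - config.read_length).astype(int), size=n_bg)
    for ci, pos in zip(bg_choice, bg_pos):
        placements.append((tid[bg_names[ci]], int(pos)))

    placements.sort()
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for i, (t, pos) in enumerate(placements):
            read = pysam.AlignedSegment(bam.header)
            read.query_name = f"read{i}"
            read.reference_id = t
            read.reference_start = pos
            read.mapping_quality = 60
            read.cigarstring = f"{config.read_length}M"
            read.query_sequence = "A" * config.read_length
            read.flag = 0
            bam.write(read)
    pysam.index(str(out_bam))
    return out_bam


def simulate_read_counts(
    config: ReadSimConfig, n_samples: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Count-level shortcut: binomial (region, background) draws per sample.

    Equivalent in distribution to counting a simulated alignment; used where
    the counting semantics themselves are not under test.
    """
    rng = rng or np.random.default_rng(config.seed)
    region = rng.binomial(config.n_reads, config.rdna_read_probability, size=n_samples)
    return pd.DataFrame(
        {"region_reads": region, "numbered_reads": config.n_reads - region}
    )


def simulate_depth_pairs(
    true_cns: np.ndarray,
    exome_depth: float = 30.0,
    subunit_bases: int = 1_871,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> list[DepthPair]:
    """Depth pairs feeding the tailored-assembly estimator.

    Mean 18S depth is ``true_cn * exome_depth / 2`` (a diploid genome shows the
    exome at copy number 2); with ``noise`` the per-base coverage is
    Poisson-resampled over the subunit span. Noise off reproduces true_cn
    exactly through the estimator.
    """
    if exome_depth <= 0:
        raise ValidationError("exome depth must be positive")
    rng = rng or np.random.default_rng(0)
    pairs = []
    for cn in np.asarray(true_cns, dtype=float):
        mean_depth = cn * exome_depth / 2.0
        if noise:
            depth_18s = rng.poisson(mean_depth * subunit_bases) / subunit_bases
        else:
            depth_18s = mean_depth
        pairs.append(DepthPair(depth_18s=float(depth_18s), depth_exome=float(exome_depth)))
    return pairs


_CATEGORY_KINSHIP_BANDS = {
    "MZ": (0.45, 0.5),
    "FIRST": (0.177, 0.354),
    "SECOND": (0.0884, 0.177),
    "THIRD": (0.0442, 0.0884),
}


def simulate_kinship_table(
    family_sizes: list[int],
    seed: int = 0,
    n_unrelated_pairs: int = 0,
    categories: list[str] | None = None,
) -> tuple[list[KinshipPair], dict]:
    """Kinship pairs with known family structure and relationship categories.

    Each family is a chain of pairs (member i with member i+1) whose kinship is
    drawn inside the requested category band (cycled from ``categories``,
    default FIRST). First-degree pairs alternate parental (IBS0 < 0.0012,
    birth gap >= 10 y) and fraternal (IBS0 well above threshold). Unrelated
    filler pairs between extra singleton ids get kinship below the third-degree
    floor. Returns (pairs, truth) where truth maps 'families' to the member
    lists and 'pair_category'/'pair_subtype' to per-pair labels.
    """
    rng = np.random.default_rng(seed)
    categories = categories or ["FIRST"]
    pairs: list[KinshipPair] = []
    truth: dict = {"families": [], "pair_category": {}, "pair_subtype": {}}
    counter = 0
    birth_years: dict[str, int] = {}
    cat_i = 0
    for size in family_sizes:
        members = [f"F{counter + j:05d}" for j in range(size)]
        counter += size
        truth["families"].append(members)
        for m in members:
            birth_years[m] = int(rng.integers(1935, 1975))
        for a, b in zip(members, members[1:]):
            cat = categories[cat_i % len(categories)]
            cat_i += 1
            low, high = _CATEGORY_KINSHIP_BANDS[cat]
            k = float(rng.uniform(low, high * 0.999))
            subtype = None
            if cat == "FIRST":
                if rng.random() < 0.5:
                    subtype = "PARENTAL"
                    ibs0 = float(rng.uniform(0, 0.0011))
                    birth_years[b] = birth_years[a] + int(rng.integers(18, 40))
                else:
                    subtype = "FRATERNAL"
                    ibs0 = float(rng.uniform(0.005, 0.05))
                    birth_years[b] = birth_years[a] + int(rng.integers(0, 8))
            elif cat == "MZ":
                ibs0 = 0.0
                birth_years[b] = birth_years[a]
            else:
                ibs0 = float(rng.uniform(0.005, 0.1))
            pair = KinshipPair(a, b, k, ibs0, birth_years[a], birth_years[b])
            pairs.append(pair)
            truth["pair_category"][(a, b)] = cat
            if subtype:
                truth["pair_subtype"][(a, b)] = subtype
    for j in range(n_unrelated_pairs):
        a, b = f"U{2 * j:05d}", f"U{2 * j + 1:05d}"
        for m in (a, b):
            birth_years[m] = int(rng.integers(1935, 1975))
        pairs.append(
            KinshipPair(a, b, float(rng.uniform(0, 0.0441)), float(rng.uniform(0.05, 0.2)),
                        birth_years[a], birth_years[b])
        )
        truth["pair_category"][(a, b)] = "UNRELATED"
    truth["birth_years"] = birth_years
    return pairs, truth


@dataclass
class CohortSimConfig:
    """Cohort generator: true copy numbers, center offsets, family blocks, trait effects.

    Defaults mirror a population with mean ~315 copies (sd 80, truncated to
    50-800, the commonly quoted ~100-600 diploid range), two sequencing centers
    with a positive Sanger-vs-deCODE ratio shift, and measurement noise of a
    few copies on the observed ratio.
    """

    n: int = 10_000
    cn_mean: float = 315.0
    cn_sd: float = 80.0
    cn_bounds: tuple[float, float] = (50.0, 800.0)
    linear_effects: dict[str, float] = field(default_factory=dict)     # trait -> standardized beta
    logistic_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    # trait -> (log-odds per SD of CN, baseline case fraction)
    center_offsets: dict[str, float] = field(default_factory=lambda: {"Sanger": 8.0, "deCODE": 0.0})
    # offsets on the copy-number-equivalent scale
    center_fractions: dict[str, float] = field(default_factory=lambda: {"Sanger": 0.5, "deCODE": 0.5})
    family_block_size: int = 0
    family_rho: float = 0.0
    measurement_sd_copies: float = 5.0
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    seasonal_null_trait: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ConfigurationError("n must be positive")
        if not -1 <= self.family_rho <= 1:
            raise ConfigurationError("family correlation must lie in [-1, 1]")
        if self.cn_sd <= 0 or self.measurement_sd_copies < 0:
            raise ConfigurationError("dispersions must be positive")


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a participant table with known effects; returns (table, truth).

    True CN: family blocks of ``family_block_size`` share a latent component so
    that CN_i = sqrt(rho) * family + sqrt(1 - rho) * individual on the z scale,
    giving intra-family correlation rho in expectation. Observed ratio =
    CN * L / G + center offset (copies scale, converted) + Gaussian measurement
    noise. Continuous traits: beta * z(CN) + N(0, 1 - beta^2) so the
    standardized regression slope equals beta. Binary traits: Bernoulli under a
    logistic link with the requested log-odds per SD of CN and baseline rate.
    An optional seasonal null trait varies with month of venepuncture while CN
    does not, for reverse-causality controls.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    if config.family_block_size > 1 and config.family_rho > 0:
        bs = config.family_block_size
        n_blocks = int(np.ceil(n / bs))
        fam_effect = np.repeat(rng.standard_normal(n_blocks), bs)[:n]
        indiv = rng.standard_normal(n)
        z = np.sqrt(config.family_rho) * fam_effect + np.sqrt(1 - config.family_rho) * indiv
        family_id = np.repeat(np.arange(n_blocks), bs)[:n]
    else:
        z = rng.standard_normal(n)
        family_id = np.arange(n)

    true_cn = np.clip(config.cn_mean + config.cn_sd * z, *config.cn_bounds)
    cn_z = (true_cn - true_cn.mean()) / true_cn.std(ddof=1)

    centers = list(config.center_offsets)
    fracs = np.array([config.center_fractions.get(c, 0) for c in centers], dtype=float)
    fracs = fracs / fracs.sum()
    center = rng.choice(centers, size=n, p=fracs)
    offset_copies = np.array([config.center_offsets[c] for c in center])

    scale = config.constants.subunit_bases / config.constants.genome_bases
    noise_copies = rng.normal(0, config.measurement_sd_copies, size=n)
    observed_ratio = (true_cn + offset_copies + noise_copies) * scale

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i:07d}" for i in range(n)],
            "true_cn": true_cn,
            "ratio": observed_ratio,
            "cn_equivalent": observed_ratio / scale,
            "center": center,
            "family_id": family_id,
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.integers(40, 70, size=n).astype(float),
        }
    ).set_index("participant_id")
    table["age_sq"] = table["age"] ** 2

    for trait, beta in config.linear_effects.items():
        if abs(beta) > 1:
            raise ConfigurationError(f"standardized beta for {trait!r} must lie in [-1, 1]")
        resid = np.sqrt(1 - beta**2)
        table[trait] = beta * cn_z + rng.normal(0, resid, size=n)

    for trait, (log_odds, base_rate) in config.logistic_effects.items():
        intercept = np.log(base_rate / (1 - base_rate))
        p = 1 / (1 + np.exp(-(intercept + log_odds * cn_z)))
        table[trait] = rng.binomial(1, p)

    if config.seasonal_null_trait:
        month = rng.integers(1, 13, size=n)
        table["month"] = month
        table[config.seasonal_null_trait] = (
            np.sin(2 * np.pi * month / 12) + rng.standard_normal(n)
        )

    truth = {
        "true_cn": true_cn,
        "cn_z": cn_z,
        "linear_effects": dict(config.linear_effects),
        "logistic_effects": dict(config.logistic_effects),
        "center_offsets": dict(config.center_offsets),
        "family_rho": config.family_rho,
        "family_id": family_id,
    }
    return table, truth
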