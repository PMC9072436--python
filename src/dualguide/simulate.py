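"""Synthetic dual-guide screens with known ground truth.

The generator emulates the statistical structure a paralog-knockout screen
analysis assumes: per-guide efficacy variation, essential-gene depletion,
synthetic-lethal interactions between paralog pairs, a multiplicative
promoter bias on the second expression position, overdispersed plasmid
abundances, multinomial sequencing, and scaffold-homology recombination.

Recombination is modeled at the molecule level: a fraction of each
construct's plasmid molecules acquire the wrong position-2 scaffold during
library/virus production. Those molecules express only the left guide, so
their descendants deplete with the left-guide-only fitness, and the reads
they emit carry a mismatched position-2 tracrRNA — which is exactly how the
read mapper detects them. Counting reads at crRNA resolution therefore mixes
the two subpopulations (diluting the signal), while sgRNA-resolution
counting (crRNA + tracrRNA both matching) recovers the intact population.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

from . import design as _design
from ._util import (DNA_ALPHABET, reverse_complement, split_rng,
                    STREAM_LIBRARY, STREAM_COUNTS, STREAM_READS,
                    STREAM_COHORT, STREAM_GUIDE_MATRIX)
from .design import Construct, GuideLibrary, GuideRecord, NEUTRAL_GENE

# Constant vector context used for read simulation and anchor-based mapping:
# [left flank | crRNA_L | tracr_L | mid linker (H1 region) | crRNA_R | tracr_R | right flank]
# Synthetic stand-ins for the vector sequence (not distributed with the paper).
VECTOR_LEFT_FLANK = "TTGTGGAAAGGACGAAACACCG"      # ends at the U6 +1 position
VECTOR_MID = "GATCCGCATATGAGATCCAGTTTCAAACGAACACCG"  # between tracr_L and crRNA_R
VECTOR_RIGHT_FLANK = "GAATTCGCTAGCTAGGTCTT"
READ_LENGTH = 150


@dataclass
class SimConfig:
    """Free parameters of the synthetic screen.

    Defaults follow the study design where stated (6 guides per gene, three
    biological replicates, 18 combinations per paralog pair via the 3/3
    positional split) and field-realistic values elsewhere.
    """

    n_essential_genes: int = 10
    n_nonessential_genes: int = 10
    n_sl_pairs: int = 5
    n_null_pairs: int = 20
    guides_per_gene: int = 6
    n_neutral_guides: int = 6
    essential_effect: float = -2.0
    sl_interaction_effect: float = -1.5
    # SD of the random fitness effect given to non-essential genes. Real
    # screens show biological spread in nonessential gene scores; 0 gives an
    # exact null (every non-essential effect identically zero).
    background_effect_sd: float = 0.0
    guide_efficacy_dist: tuple[float, float] = (5.0, 2.0)  # Beta(a, b) on [0, 1]
    promoter_bias: float = 0.85  # multiplicative efficacy factor, position 2 (H1)
    recombination_rate: float = 0.0
    pdna_abundance_dispersion: float = 0.1  # gamma variance of relative abundance
    sequencing_depth: int = 1000  # mean read pairs per construct per sample
    n_replicates: int = 3
    enzyme: str = "spCas9"
    tracr_combination: tuple[str, str] = ("VCR1", "WCR3")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_essential_genes", "n_nonessential_genes", "n_sl_pairs",
                     "n_null_pairs", "guides_per_gene", "n_neutral_guides",
                     "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.guides_per_gene and self.guides_per_gene % 2:
            raise ValueError("guides_per_gene must be even (the pairing scheme "
                             "splits each gene's guides into two halves)")
        for name in ("recombination_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.promoter_bias <= 1.5:
            raise ValueError("promoter_bias must be a positive efficacy factor")
        if self.pdna_abundance_dispersion <= 0:
            raise ValueError("pdna_abundance_dispersion must be positive")
        a, b = self.guide_efficacy_dist
        if a <= 0 or b <= 0:
            raise ValueError("guide_efficacy_dist must be valid Beta parameters")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["guide_efficacy_dist"] = list(d["guide_efficacy_dist"])
        d["tracr_combination"] = list(d["tracr_combination"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["guide_efficacy_dist"] = tuple(d["guide_efficacy_dist"])
        d["tracr_combination"] = tuple(d["tracr_combination"])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth behind a simulated screen."""

    gene_effect: dict[str, float]
    interaction_effect: dict[tuple[str, str], float]
    guide_efficacy: dict[str, float]
    construct_true_lfc: pd.Series  # expected LFC of the intact molecule
    construct_left_only_lfc: pd.Series  # expected LFC if only the left guide acts
    recombination_rate: float

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "construct_id": self.construct_true_lfc.index,
            "true_lfc": self.construct_true_lfc.values,
            "left_only_lfc": self.construct_left_only_lfc.values,
        })
        df.to_csv(path, index=False)


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random spacers over ACGT."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = "".join(rng.choice(list(DNA_ALPHABET), size=length))
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))


def construct_expected_lfc(c: Construct, gene_effect: dict[str, float],
                           interaction_effect: dict[tuple[str, str], float],
                           guide_efficacy: dict[str, float],
                           promoter_bias: float) -> tuple[float, float]:
    """(intact LFC, left-only LFC) for one construct.

    intact = eff_L * e(gene_L) + eff_R' * e(gene_R) + eff_L * eff_R' * i(pair)
    with eff_R' = eff_R * promoter_bias; an inert guide (efficacy 0) nullifies
    both its single term and the interaction term.
    """
    eff_l = guide_efficacy.get(c.crRNA_left, 1.0)
    eff_r = guide_efficacy.get(c.crRNA_right, 1.0) * promoter_bias
    e_l = gene_effect.get(c.gene_left, 0.0)
    e_r = gene_effect.get(c.gene_right, 0.0)
    inter = interaction_effect.get(_pair_key(c.gene_left, c.gene_right), 0.0)
    full = eff_l * e_l + eff_r * e_r + eff_l * eff_r * inter
    left_only = eff_l * e_l
    return full, left_only


def simulate_library(config: SimConfig) -> tuple[GuideLibrary, TruthTable]:
    """Generate a dual-guide library plus its ground truth.

    Gene classes: essential genes (single effect = essential_effect),
    nonessential genes (0), synthetic-lethal pairs (singles 0, interaction =
    sl_interaction_effect) and null pairs (everything 0). Every gene also
    appears in single-gene constructs partnered with a neutral cutting
    control in both positions.
    """
    rng = split_rng(config.seed, STREAM_LIBRARY)
    spacer_len = _design.SPACER_LEN[config.enzyme]

    ess = [f"ESS{i:03d}" for i in range(config.n_essential_genes)]
    non = [f"NON{i:03d}" for i in range(config.n_nonessential_genes)]
    sl_pairs = [(f"SLA{i:03d}", f"SLB{i:03d}") for i in range(config.n_sl_pairs)]
    null_pairs = [(f"NPA{i:03d}", f"NPB{i:03d}") for i in range(config.n_null_pairs)]
    pair_genes = [g for p in sl_pairs + null_pairs for g in p]
    genes = ess + non + pair_genes

    if config.background_effect_sd > 0:
        gene_effect = {g: float(rng.normal(0.0, config.background_effect_sd))
                       for g in genes}
    else:
        gene_effect = {g: 0.0 for g in genes}
    gene_effect.update({g: config.essential_effect for g in ess})
    gene_effect[NEUTRAL_GENE] = 0.0
    interaction = {_pair_key(*p): config.sl_interaction_effect for p in sl_pairs}
    interaction.update({_pair_key(*p): 0.0 for p in null_pairs})

    n_guides = len(genes) * config.guides_per_gene + config.n_neutral_guides
    spacers = _random_spacers(rng, n_guides, spacer_len)
    a, b = config.guide_efficacy_dist

    guides: dict[str, list[GuideRecord]] = {}
    efficacy: dict[str, float] = {}
    i = 0
    for g in genes:
        recs = []
        for j in range(config.guides_per_gene):
            sp = spacers[i]; i += 1
            recs.append(GuideRecord(guide_id=f"{g}_g{j + 1}", gene=g, spacer=sp,
                                    gpp_pick_order=j + 1))
            efficacy[sp] = float(rng.beta(a, b))
        guides[g] = recs
    neutral = []
    for j in range(config.n_neutral_guides):
        sp = spacers[i]; i += 1
        neutral.append(GuideRecord(guide_id=f"{NEUTRAL_GENE}_g{j + 1}", gene=NEUTRAL_GENE,
                                   spacer=sp, gpp_pick_order=j + 1))
        efficacy[sp] = 1.0  # cutting control: cuts, but the locus is neutral

    constructs: list[Construct] = []
    for g in genes:
        constructs.extend(_design.design_single_constructs(
            guides[g], neutral, config.tracr_combination, config.enzyme,
            both_positions=True, include_controls=False))
    for ga, gb in sl_pairs + null_pairs:
        constructs.extend(_design.design_pair_constructs(
            guides[ga], guides[gb], config.tracr_combination, config.enzyme))
    if neutral:
        constructs.extend(_design.design_single_constructs(
            [], neutral, config.tracr_combination, config.enzyme,
            include_controls=True))

    library = GuideLibrary(constructs=constructs, enzyme=config.enzyme,
                           tracr_combination=config.tracr_combination)

    full, left_only = {}, {}
    for c in constructs:
        f, l = construct_expected_lfc(c, gene_effect, interaction, efficacy,
                                      config.promoter_bias)
        full[c.construct_id] = f
        left_only[c.construct_id] = l
    ids = library.construct_ids
    truth = TruthTable(
        gene_effect=gene_effect,
        interaction_effect=interaction,
        guide_efficacy=efficacy,
        construct_true_lfc=pd.Series(full).reindex(ids),
        construct_left_only_lfc=pd.Series(left_only).reindex(ids),
        recombination_rate=config.recombination_rate,
    )
    return library, truth


@dataclass
class ScreenCounts:
    """Construct-level counts plus the intact (non-recombined) subcounts.

    counts.loc[c, s] is what crRNA-resolution sequencing of sample s would
    report for construct c; intact.loc[c, s] is the subset of molecules whose
    position-2 scaffold is still the designed one (what sgRNA-resolution
    counting recovers).
    """

    counts: pd.DataFrame
    intact: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("construct_id").to_csv(path, sep="\t")


def simulate_counts(library: GuideLibrary, truth: TruthTable,
                    config: SimConfig) -> ScreenCounts:
    """Draw pDNA and gDNA replicate counts.

    pDNA: gamma-weighted multinomial (Dirichlet-multinomial overdispersion);
    a binomial fraction recombination_rate of each construct's molecules is
    marked recombined. gDNA replicates: multinomial over the two
    subpopulations with proportions pDNA_sub * 2^(sub LFC), at
    sequencing_depth * n_constructs total.
    """
    if config.sequencing_depth <= 0:
        raise ValueError("sequencing_depth must be positive")
    rng = split_rng(config.seed, STREAM_COUNTS)
    ids = library.construct_ids
    n = len(ids)
    total = config.sequencing_depth * n

    disp = config.pdna_abundance_dispersion
    w = rng.gamma(shape=1.0 / disp, scale=disp, size=n)
    pdna = rng.multinomial(total, w / w.sum())
    pdna_intact = rng.binomial(pdna, 1.0 - config.recombination_rate)
    pdna_rec = pdna - pdna_intact

    lfc_full = truth.construct_true_lfc.reindex(ids).to_numpy()
    lfc_left = truth.construct_left_only_lfc.reindex(ids).to_numpy()

    counts = {"pDNA": pdna}
    intact = {"pDNA": pdna_intact}
    for r in range(1, config.n_replicates + 1):
        w_int = pdna_intact * np.exp2(lfc_full)
        w_rec = pdna_rec * np.exp2(lfc_left)
        w_all = np.concatenate([w_int, w_rec])
        s = w_all.sum()
        if s == 0:
            raise ValueError("degenerate screen: zero total abundance")
        draw = rng.multinomial(total, w_all / s)
        counts[f"rep{r}"] = draw[:n] + draw[n:]
        intact[f"rep{r}"] = draw[:n]
    cdf = pd.DataFrame(counts, index=pd.Index(ids, name="construct_id"))
    idf = pd.DataFrame(intact, index=pd.Index(ids, name="construct_id"))
    return ScreenCounts(counts=cdf, intact=idf)


def cassette_sequence(c: Construct, tracr_sequences: dict[str, str]) -> str:
    """Full vector-context sequence of one construct's dual-guide cassette."""
    return (VECTOR_LEFT_FLANK + c.crRNA_left + tracr_sequences[c.tracr_left]
            + VECTOR_MID + c.crRNA_right + tracr_sequences[c.tracr_right]
            + VECTOR_RIGHT_FLANK)


def _read_pair_for(c: Construct, tracr_sequences: dict[str, str],
                   tracr_right_override: str | None, stagger: int) -> tuple[str, str]:
    tr_r = tracr_right_override if tracr_right_override is not None else c.tracr_right
    seg1 = ("N" * 0 + VECTOR_LEFT_FLANK + c.crRNA_left
            + tracr_sequences[c.tracr_left] + VECTOR_MID)
    r1 = ("ACGT" * 2)[:stagger] + seg1
    seg2 = (VECTOR_MID + c.crRNA_right + tracr_sequences[tr_r]
            + VECTOR_RIGHT_FLANK)
    r2 = reverse_complement(seg2)
    return r1[:READ_LENGTH], r2[:READ_LENGTH]


def simulate_read_pairs(library: GuideLibrary, counts: ScreenCounts,
                        config: SimConfig, sample: str = "pDNA",
                        n_read_pairs: int | None = None,
                        stagger: bool = True) -> Iterator[tuple[str, str, str]]:
    """Yield (name, read1, read2) for one sample.

    Read 1 covers the position-1 crRNA and its tracrRNA; read 2 covers the
    position-2 crRNA and its tracrRNA, reverse-complemented. Recombined
    molecules carry the position-1 (partner) tracrRNA of a uniformly random
    other construct in position 2, leaving both crRNAs intact. A 0-8 nt
    stagger prefix emulates the stagger primer mix on read 1.
    """
    spacer_len = _design.SPACER_LEN[library.enzyme]
    min_len = len(VECTOR_LEFT_FLANK) + spacer_len + 12
    if READ_LENGTH < min_len:
        raise ValueError("read length too short to cover anchor + spacer + scaffold prefix")
    rng = split_rng(config.seed, STREAM_READS)
    constructs = library.constructs
    n_int = counts.intact[sample].reindex(library.construct_ids).to_numpy()
    n_tot = counts.counts[sample].reindex(library.construct_ids).to_numpy()
    n_rec = n_tot - n_int
    if n_read_pairs is not None:
        tot = n_tot.sum()
        if tot == 0:
            raise ValueError(f"sample {sample!r} has no reads")
        w = np.concatenate([n_int, n_rec]).astype(float) / tot
        draw = rng.multinomial(n_read_pairs, w)
        n_int, n_rec = draw[:len(constructs)], draw[len(constructs):]

    k = 0
    n_constructs = len(constructs)
    for i, c in enumerate(constructs):
        staggers = rng.integers(0, 9, size=int(n_int[i]) + int(n_rec[i])) if stagger \
            else np.zeros(int(n_int[i]) + int(n_rec[i]), dtype=int)
        for j in range(int(n_int[i])):
            r1, r2 = _read_pair_for(c, library.tracr_sequences, None, int(staggers[j]))
            yield f"sim:{k}", r1, r2
            k += 1
        for j in range(int(n_rec[i])):
            donor = constructs[int(rng.integers(0, n_constructs - 1))]
            if donor is c:
                donor = constructs[-1]
            r1, r2 = _read_pair_for(c, library.tracr_sequences, donor.tracr_left,
                                    int(staggers[int(n_int[i]) + j]))
            yield f"sim:{k}", r1, r2
            k += 1


def write_fastq_pair(read_pairs: Iterable[tuple[str, str, str]],
                     r1_path, r2_path) -> int:
    """Write paired 4-line FASTQ records (gzip if the path ends in .gz)."""
    def _open(p):
        return gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")
    n = 0
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for name, r1, r2 in read_pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# DepMap-like cohort for control/paralog selection

@dataclass
class CohortConfig:
    """Synthetic cell-line cohort emulating dependency-probability, copy
    number, mutation and expression matrices."""

    n_lines: int = 200
    n_pairs: int = 50
    n_sl_pairs: int = 10
    n_silent_pairs: int = 5  # non-SL pairs silenced in expression
    n_essential_genes: int = 15
    n_nonessential_genes: int = 15
    lof_fraction: float = 0.12  # fraction of lines with partner loss per pair
    sl_dependency: tuple[float, float] = (12.0, 2.0)   # Beta in LOF lines
    background_dependency: tuple[float, float] = (1.0, 12.0)  # Beta elsewhere
    cn_sd: float = 0.2
    cn_loss: float = -1.5
    seed: int = 0


@dataclass
class SyntheticCohort:
    dep_crispr: pd.DataFrame
    dep_rnai: pd.DataFrame
    cn_log2: pd.DataFrame
    mutations: pd.DataFrame  # variant class strings; "" = none
    expression: pd.DataFrame  # log2(TPM + 1)
    pairs: list[tuple[str, str]]
    true_sl_pairs: set[tuple[str, str]]
    silent_pairs: set[tuple[str, str]]
    essential_genes: list[str]
    nonessential_genes: list[str]


def simulate_depmap_cohort(config: CohortConfig) -> SyntheticCohort:
    """Cohort with planted synthetic-lethal pairs.

    For a planted pair (A, B), a subset of lines loses B (deep copy-number
    loss or a truncating mutation) and those lines depend strongly on A;
    everywhere else dependency is background noise. Non-planted pairs get
    LOF lines whose dependency stays at background.
    """
    rng = split_rng(config.seed, STREAM_COHORT)
    lines = [f"CL{i:03d}" for i in range(config.n_lines)]
    pairs = [(f"PRA{i:03d}", f"PRB{i:03d}") for i in range(config.n_pairs)]
    true_sl = set(pairs[:config.n_sl_pairs])
    ess = [f"CESS{i:03d}" for i in range(config.n_essential_genes)]
    non = [f"CNON{i:03d}" for i in range(config.n_nonessential_genes)]
    genes = [g for p in pairs for g in p] + ess + non

    a0, b0 = config.background_dependency
    a1, b1 = config.sl_dependency
    dep = pd.DataFrame(rng.beta(a0, b0, size=(config.n_lines, len(genes))),
                       index=lines, columns=genes)
    dep_rnai = pd.DataFrame(rng.beta(a0, b0, size=(config.n_lines, len(genes))),
                            index=lines, columns=genes)
    # essential genes: near-certain dependency almost everywhere, both datasets
    for g in ess:
        dep[g] = rng.beta(30.0, 1.0, size=config.n_lines)
        dep_rnai[g] = rng.uniform(0.5, 1.0, size=config.n_lines)

    cn = pd.DataFrame(rng.normal(0.0, config.cn_sd, size=(config.n_lines, len(genes))),
                      index=lines, columns=genes)
    mut = pd.DataFrame("", index=lines, columns=genes)
    # background mutation noise (non-deleterious)
    bg = rng.random(size=mut.shape) < 0.02
    mut = mut.mask(pd.DataFrame(bg, index=lines, columns=genes), "missense")

    n_lof = max(3, int(round(config.lof_fraction * config.n_lines)))
    for (ga, gb) in pairs:
        lof_lines = rng.choice(config.n_lines, size=n_lof, replace=False)
        for li in lof_lines:
            if rng.random() < 0.5:
                cn.iloc[li, cn.columns.get_loc(gb)] = config.cn_loss
            else:
                cls = "frameshift" if rng.random() < 0.5 else "nonsense"
                mut.iloc[li, mut.columns.get_loc(gb)] = cls
        if (ga, gb) in true_sl:
            dep.iloc[lof_lines, dep.columns.get_loc(ga)] = rng.beta(a1, b1, size=n_lof)

    expr = pd.DataFrame(rng.gamma(2.0, 1.5, size=(config.n_lines, len(genes))),
                        index=lines, columns=genes)
    # a few non-SL pairs silenced in expression (negative-control pair set)
    silent = set(pairs[config.n_sl_pairs:config.n_sl_pairs + config.n_silent_pairs])
    for ga, gb in silent:
        for g in (ga, gb):
            expr[g] = np.where(rng.random(config.n_lines) < 0.95, 0.0,
                               rng.gamma(2.0, 1.5, size=config.n_lines))
    # nonessential control genes: silenced nearly everywhere
    for g in non:
        expr[g] = np.where(rng.random(config.n_lines) < 0.95, 0.0,
                           rng.gamma(2.0, 1.5, size=config.n_lines))
        dep[g] = rng.beta(1.0, 30.0, size=config.n_lines)
        dep_rnai[g] = rng.beta(1.0, 30.0, size=config.n_lines)

    return SyntheticCohort(dep_crispr=dep, dep_rnai=dep_rnai, cn_log2=cn,
                           mutations=mut, expression=expr, pairs=pairs,
                           true_sl_pairs=true_sl, silent_pairs=silent,
                           essential_genes=ess, nonessential_genes=non)


# ---------------------------------------------------------------------------
# Guide x cell-line LFC matrix for the consistency classifier

def simulate_guide_lfc_matrix(n_genes: int = 100, guides_per_gene: int = 4,
                              n_lines: int = 30, gene_sd: float = 1.0,
                              guide_noise_sd: float = 0.3,
                              inert_fraction: float = 0.0,
                              seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Guide-level LFC profiles with a shared per-gene signal.

    Each gene gets a cell-line profile ~ N(0, gene_sd^2); each of its guides
    observes that profile plus independent N(0, guide_noise_sd^2) noise.
    A fraction of guides are inert (pure noise), emulating inefficacious
    guides that should fail the consistency selection.
    Returns (matrix guides x lines, guide -> gene map).
    """
    rng = split_rng(seed, STREAM_GUIDE_MATRIX)
    rows, gmap = [], {}
    for i in range(n_genes):
        gene = f"G{i:04d}"
        profile = rng.normal(0.0, gene_sd, size=n_lines)
        for j in range(guides_per_gene):
            gid = f"{gene}_g{j + 1}"
            gmap[gid] = gene
            if rng.random() < inert_fraction:
                rows.append(pd.Series(rng.normal(0.0, guide_noise_sd, size=n_lines), name=gid))
            else:
                rows.append(pd.Series(profile + rng.normal(0.0, guide_noise_sd, size=n_lines),
                                      name=gid))
    mat = pd.DataFrame(rows)
    mat.columns = [f"CL{k:03d}" for k in range(n_lines)]
    return mat, pd.Series(gmap, name="gene")
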