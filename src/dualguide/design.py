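"""Dual-guide library design: guide prioritization, off-target filtering,
pairing scheme, and oligo assembly.

A dual-guide construct is one lentiviral cassette expressing two guides: the
left guide from a U6 promoter and the right guide from an H1 promoter, each
fused to its own tracrRNA scaffold. Using two divergent scaffolds (e.g.
VCR1 + WCR3) suppresses template recombination between the homologous
constant regions during vector/virus production.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd

from ._util import reverse_complement, validate_spacer

# Printed synthesis templates. The Cas9 oligo carries the left spacer in
# sense orientation and the right spacer reverse-complemented between three
# constant segments (32 + 20 + 31 + 20 + 32 = 135 nt). The Cas12a oligo
# carries both 23-nt spacers in sense orientation around the direct repeat
# (31 + 23 + 20 + 23 + 37 = 134 nt).
CAS9_OLIGO_5P = "AGGCACTTGCTCGTACGACGCGTCTCGCACCG"
CAS9_OLIGO_MID = "GTTTCAGTCTTCCGGCGAAGACACCTGAAAC"
CAS9_OLIGO_3P = "CGGGAAGAGACGTTAAGGTGCCGGGCCCACAT"

CAS12A_OLIGO_5P = "AGGCACTTGCTCGTACGACGCGTCTCAAGAT"
CAS12A_DIRECT_REPEAT = "TAATTTCTACTGTCGTAGAT"
CAS12A_OLIGO_3P = "TTTTTTGAATCGAGACGTTAAGGTGCCGGGCCCACAT"

SPACER_LEN = {"spCas9": 20, "enCas12a": 23}

NEUTRAL_GENE = "AAVS1"

# Synthetic stand-in scaffold sequences for the named tracrRNA variants.
# The real variant sequences are not distributed with this package; these
# are random, mutually divergent 60-mers (distinct from the first base) so
# that scaffold identity is resolvable from a short read prefix. Users with
# the real sequences can pass their own mapping anywhere a tracr set is
# accepted.
DEFAULT_TRACR_SEQUENCES = {
    "VCR1": "TACTCTCCGCCACAATGTCAGGAAATCCGCAGCGCGAGAGGCTATAGCAAGCTTTACCTA",
    "WCR2": "CAGCGAGTAGCCAGTTTGAGGCAGGGTGTACAGTCATCTAATCCGAAGCTTCAGCTGCGA",
    "WCR3": "AGTAGAAGAGCTTTTTCTTTACGCCAAATTACCTTACCTAGACTGGACTTTTGGGAGATG",
    "SCR27": "GTTAATACGCCGCGGACTATTATATCCCGCATAGGAGGCTCCTCAAAGCGAAAATGAGCG",
    "SCR43": "TCGAAAAATAGTGAATGATCACGATCACGTCGGTAAGTGCGTCAGTCTGACCACACTGTT",
    "canonical": "CTGGATCACTATTCTGTAGGCACGCGAGACTACTTGTACAGACCAACAGGCAGTCAAGGA",
}

LIBRARY_CSV_COLUMNS = [
    "construct_id", "category", "gene_left", "gene_right",
    "crRNA_left", "crRNA_right", "tracr_left", "tracr_right",
    "promoter_left", "promoter_right", "oligo",
]


@dataclass
class GuideRecord:
    """One candidate guide for one gene.

    source_tier reflects where the guide came from: 'validated' guides have
    empirical screen evidence of consistent on-target behaviour, 'pfam_top'
    guides hit an annotated protein domain with a high design rank, and
    'gpp_rank' guides are ranked only by the design tool's pick order.
    Off-target counts come from an external genome-wide search (the intended
    site excluded) under the enzyme's PAM scope.
    """

    guide_id: str
    gene: str
    spacer: str
    source_tier: str = "gpp_rank"
    gpp_pick_order: int = 1
    pfam_hit: bool = False
    consistency_score: float | None = None
    offtarget_0mm: int = 0
    offtarget_1mm: int = 0

    def __post_init__(self) -> None:
        if self.gpp_pick_order < 1:
            raise ValueError("gpp_pick_order must be >= 1")
        if self.source_tier not in ("validated", "pfam_top", "gpp_rank"):
            raise ValueError(f"unknown source_tier {self.source_tier!r}")


@dataclass
class Construct:
    construct_id: str
    category: str  # pair | single_left | single_right | control
    gene_left: str
    gene_right: str
    crRNA_left: str
    crRNA_right: str
    tracr_left: str
    tracr_right: str
    promoter_left: str = "U6"
    promoter_right: str = "H1"
    oligo: str = ""


@dataclass
class GuideLibrary:
    """A designed dual-guide library: constructs plus enzyme and scaffold pair."""

    constructs: list[Construct]
    enzyme: str = "spCas9"
    tracr_combination: tuple[str, str] = ("VCR1", "WCR3")
    tracr_sequences: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRACR_SEQUENCES)
    )

    def __post_init__(self) -> None:
        ids = [c.construct_id for c in self.constructs]
        if len(set(ids)) != len(ids):
            raise ValueError("construct_ids are not unique")

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    @property
    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(c) for c in self.constructs])
        return df.reindex(columns=LIBRARY_CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, enzyme: str = "spCas9",
                 tracr_sequences: dict[str, str] | None = None) -> "GuideLibrary":
        df = pd.read_csv(path, dtype=str).fillna("")
        constructs = [Construct(**row) for row in df[LIBRARY_CSV_COLUMNS].to_dict("records")]
        tracrs = tuple(dict.fromkeys((c.tracr_left, c.tracr_right) for c in constructs))
        combo = tracrs[0] if tracrs else ("VCR1", "WCR3")
        return cls(constructs=constructs, enzyme=enzyme, tracr_combination=combo,
                   tracr_sequences=tracr_sequences or dict(DEFAULT_TRACR_SEQUENCES))


@dataclass
class PrioritizationResult:
    ranked: list[GuideRecord]
    shortfall: int  # how many guides short of n_required (0 if satisfied)


def _tier_key(g: GuideRecord) -> tuple:
    """Three-tier comparator: validated guides first, then domain-targeting
    guides that keep a design rank within the top 20, then everything else by
    pick order. Ties break by pick order then guide_id (stable total preorder).
    """
    if g.source_tier == "validated":
        tier = 0
    elif g.pfam_hit and g.gpp_pick_order <= 20:
        tier = 1
    else:
        tier = 2
    return (tier, g.gpp_pick_order, g.guide_id)


def prioritize_guides(candidates: Sequence[GuideRecord], n_required: int) -> PrioritizationResult:
    """Rank one gene's candidate guides and take the top n_required."""
    genes = {g.gene for g in candidates}
    if len(genes) > 1:
        raise ValueError(f"candidates span multiple genes: {sorted(genes)}")
    ranked = sorted(candidates, key=_tier_key)
    top = ranked[:n_required]
    return PrioritizationResult(ranked=top, shortfall=max(0, n_required - len(top)))


@dataclass
class OfftargetFilterResult:
    kept: list[GuideRecord]
    loosened: set[str]  # guide_ids re-admitted under the relaxed rule
    removed: list[GuideRecord]


def filter_offtargets(guides: Sequence[GuideRecord], enzyme: str,
                      guides_per_gene: int | None = None) -> OfftargetFilterResult:
    """Drop guides with any perfect-match or 1-mismatch off-target site.

    Off-target counts are taken as provided (already restricted to the
    enzyme's PAM scope by the external search). If a gene would fall below
    guides_per_gene survivors, guides with no perfect-match site are
    re-admitted in pick order under the relaxed rule (tolerating 1 mismatch)
    and flagged.
    """
    if enzyme not in SPACER_LEN:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    for g in guides:
        for col in ("offtarget_0mm", "offtarget_1mm"):
            if getattr(g, col) is None:
                raise ValueError(f"guide {g.guide_id}: missing off-target column {col!r}")

    kept = [g for g in guides if g.offtarget_0mm == 0 and g.offtarget_1mm == 0]
    removed = [g for g in guides if g not in kept]
    loosened: set[str] = set()

    if guides_per_gene is not None:
        by_gene: dict[str, list[GuideRecord]] = {}
        for g in guides:
            by_gene.setdefault(g.gene, []).append(g)
        for gene, gene_guides in by_gene.items():
            clean = [g for g in gene_guides if g in kept]
            if len(clean) >= guides_per_gene:
                continue
            candidates = sorted(
                (g for g in gene_guides if g not in clean and g.offtarget_0mm == 0),
                key=lambda g: (g.gpp_pick_order, g.guide_id),
            )
            needed = guides_per_gene - len(clean)
            for g in candidates[:needed]:
                kept.append(g)
                loosened.add(g.guide_id)
                removed.remove(g)

    order = {id(g): i for i, g in enumerate(guides)}
    kept.sort(key=lambda g: order[id(g)])
    return OfftargetFilterResult(kept=kept, loosened=loosened, removed=removed)


def _make_construct(category: str, g_left: GuideRecord, g_right: GuideRecord,
                    tracr_combination: tuple[str, str], enzyme: str) -> Construct:
    cid = f"{g_left.gene}~{g_left.guide_id}|{g_right.gene}~{g_right.guide_id}"
    oligo = assemble_oligo(g_left.spacer, g_right.spacer, enzyme)
    return Construct(
        construct_id=cid, category=category,
        gene_left=g_left.gene, gene_right=g_right.gene,
        crRNA_left=g_left.spacer, crRNA_right=g_right.spacer,
        tracr_left=tracr_combination[0], tracr_right=tracr_combination[1],
        oligo=oligo,
    )


def design_pair_constructs(guides_a: Sequence[GuideRecord], guides_b: Sequence[GuideRecord],
                           tracr_combination: tuple[str, str] = ("VCR1", "WCR3"),
                           enzyme: str = "spCas9") -> list[Construct]:
    """All cross-combinations for one paralog pair under the positional split.

    Each gene's guides (in priority order) are split into a left half and a
    right half; constructs are A-left x B-right plus B-left x A-right, giving
    (g/2)^2 * 2 constructs for g guides per gene — 18 when g = 6.
    """
    if len(guides_a) != len(guides_b):
        raise ValueError("both genes must contribute the same number of guides")
    g = len(guides_a)
    if g == 0 or g % 2:
        raise ValueError(f"guides per gene must be a positive even count, got {g}")
    half = g // 2
    out = []
    for ga in guides_a[:half]:
        for gb in guides_b[half:]:
            out.append(_make_construct("pair", ga, gb, tracr_combination, enzyme))
    for gb in guides_b[:half]:
        for ga in guides_a[half:]:
            out.append(_make_construct("pair", gb, ga, tracr_combination, enzyme))
    return out


def design_single_constructs(guides: Sequence[GuideRecord],
                             neutral_guides: Sequence[GuideRecord],
                             tracr_combination: tuple[str, str] = ("VCR1", "WCR3"),
                             enzyme: str = "spCas9",
                             both_positions: bool = True,
                             include_controls: bool = True) -> list[Construct]:
    """Single-gene constructs: each guide partnered with a neutral cutting
    control (round-robin over the neutral guides), in the left position and —
    by default — also in the right position; plus neutral-neutral controls.
    """
    if not neutral_guides:
        raise ValueError("at least one neutral control guide is required")
    out = []
    n = len(neutral_guides)
    for i, g in enumerate(guides):
        c = _make_construct("single_left", g, neutral_guides[i % n], tracr_combination, enzyme)
        out.append(c)
        if both_positions:
            c = _make_construct("single_right", neutral_guides[i % n], g, tracr_combination, enzyme)
            out.append(c)
    if include_controls:
        for i, g in enumerate(neutral_guides):
            out.append(_make_construct("control", g, neutral_guides[(i + 1) % n],
                                       tracr_combination, enzyme))
    return out


def assemble_oligo_cas9(crRNA_left: str, crRNA_right: str) -> str:
    """135-nt Cas9 synthesis oligo: left spacer sense, right spacer
    reverse-complemented, between the printed constant segments."""
    validate_spacer(crRNA_left, 20)
    validate_spacer(crRNA_right, 20)
    return (CAS9_OLIGO_5P + crRNA_left + CAS9_OLIGO_MID
            + reverse_complement(crRNA_right) + CAS9_OLIGO_3P)


def assemble_oligo_cas12a(crRNA_1: str, crRNA_2: str) -> str:
    """134-nt Cas12a synthesis oligo: both 23-nt spacers in sense orientation
    around the engineered direct repeat."""
    validate_spacer(crRNA_1, 23)
    validate_spacer(crRNA_2, 23)
    return CAS12A_OLIGO_5P + crRNA_1 + CAS12A_DIRECT_REPEAT + crRNA_2 + CAS12A_OLIGO_3P


def assemble_oligo(crRNA_left: str, crRNA_right: str, enzyme: str) -> str:
    if enzyme == "spCas9":
        return assemble_oligo_cas9(crRNA_left, crRNA_right)
    if enzyme == "enCas12a":
        return assemble_oligo_cas12a(crRNA_left, crRNA_right)
    raise ValueError(f"unknown enzyme {enzyme!r}")


def parse_oligo(oligo: str, enzyme: str) -> tuple[str, str]:
    """Recover (crRNA_left, crRNA_right) from an assembled oligo by anchoring
    on the constant segments (round-trip inverse of assemble_oligo)."""
    if enzyme == "spCas9":
        p5, mid, p3, k = CAS9_OLIGO_5P, CAS9_OLIGO_MID, CAS9_OLIGO_3P, 20
    elif enzyme == "enCas12a":
        p5, mid, p3, k = CAS12A_OLIGO_5P, CAS12A_DIRECT_REPEAT, CAS12A_OLIGO_3P, 23
    else:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    if not (oligo.startswith(p5) and oligo.endswith(p3)):
        raise ValueError("oligo does not match the constant segments")
    a = len(p5)
    left = oligo[a:a + k]
    if oligo[a + k:a + k + len(mid)] != mid:
        raise ValueError("internal constant segment does not match")
    slot2 = oligo[a + k + len(mid):a + 2 * k + len(mid)]
    right = reverse_complement(slot2) if enzyme == "spCas9" else slot2
    return left, right


def guides_from_csv(path) -> list[GuideRecord]:
    """Read candidate guides from a CSV mirroring the GuideRecord fields."""
    df = pd.read_csv(path)
    records = []
    for row in df.to_dict("records"):
        row = {k: v for k, v in row.items() if k in GuideRecord.__dataclass_fields__}
        if "consistency_score" in row and pd.isna(row["consistency_score"]):
            row["consistency_score"] = None
        row["pfam_hit"] = bool(row.get("pfam_hit", False))
        records.append(GuideRecord(**row))
    return records
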