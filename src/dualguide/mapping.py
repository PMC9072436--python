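"""Assign paired-end reads to dual-guide constructs and estimate the
template-recombination rate.

Mapping is anchor-based rather than alignment-based: the amplicon structure
is fully known, so each read is scanned (over 0-8 nt of stagger) for the
constant vector flank, the spacer is extracted at a fixed offset, and the
k nt that follow it are compared against the construct's expected tracrRNA
prefix. A read pair whose two crRNAs resolve a construct but whose scaffold
prefix does not match is evidence of recombination between the homologous
scaffold regions (the ratio of sgRNA-resolution to crRNA-resolution mapped
reads measures the recombination rate).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import design as _design
from ._util import hamming, reverse_complement
from .design import GuideLibrary
from .simulate import VECTOR_LEFT_FLANK, VECTOR_MID

MAX_STAGGER = 8


@dataclass
class ReferenceIndex:
    """Lookup tables from spacers/scaffold prefixes to constructs."""

    spacer_len: int
    tracr_k: int
    left_anchor: str
    right_anchor: str
    left_spacers: dict[str, set[str]]          # spacer -> construct ids
    right_spacers: dict[str, set[str]]
    pair_lookup: dict[tuple[str, str], str]    # (crL, crR) -> construct id
    tracr_prefix: dict[str, str]               # tracr_id -> first k nt
    expected_tracrs: dict[str, tuple[str, str]]  # construct id -> (tracrL, tracrR)
    construct_ids: list[str]
    min_disambiguating_k: int


def _min_disambiguating_k(seqs: list[str]) -> int:
    """Smallest prefix length at which all sequences are pairwise distinct."""
    k = 1
    maxlen = max(len(s) for s in seqs)
    while k <= maxlen:
        prefixes = {s[:k] for s in seqs}
        if len(prefixes) == len(seqs):
            return k
        k += 1
    raise ValueError("tracr sequences are not pairwise distinct")


def build_reference(library: GuideLibrary, tracr_prefix_len: int = 10) -> ReferenceIndex:
    """Index a library for read assignment.

    Errors if the library's tracr sequences cannot be told apart within the
    first tracr_prefix_len bases (the error names the k that would work).
    """
    spacer_len = _design.SPACER_LEN[library.enzyme]
    used_tracrs = sorted({t for c in library for t in (c.tracr_left, c.tracr_right)})
    seqs = [library.tracr_sequences[t] for t in used_tracrs]
    if len(seqs) > 1:
        if len({s for s in seqs}) != len(seqs):
            raise ValueError("two tracr ids share an identical sequence; "
                             "scaffolds are indistinguishable at any k")
        min_k = _min_disambiguating_k(seqs)
        if tracr_prefix_len < min_k:
            raise ValueError(f"tracr prefixes collide at k={tracr_prefix_len}; "
                             f"need k >= {min_k}")
    else:
        min_k = 1

    left: dict[str, set[str]] = {}
    right: dict[str, set[str]] = {}
    pair: dict[tuple[str, str], str] = {}
    expected: dict[str, tuple[str, str]] = {}
    for c in library:
        left.setdefault(c.crRNA_left, set()).add(c.construct_id)
        right.setdefault(c.crRNA_right, set()).add(c.construct_id)
        key = (c.crRNA_left, c.crRNA_right)
        if key in pair:
            raise ValueError(f"duplicate crRNA pair for constructs "
                             f"{pair[key]} and {c.construct_id}")
        pair[key] = c.construct_id
        expected[c.construct_id] = (c.tracr_left, c.tracr_right)

    prefixes = {t: library.tracr_sequences[t][:tracr_prefix_len] for t in used_tracrs}
    return ReferenceIndex(
        spacer_len=spacer_len, tracr_k=tracr_prefix_len,
        left_anchor=VECTOR_LEFT_FLANK, right_anchor=VECTOR_MID,
        left_spacers=left, right_spacers=right, pair_lookup=pair,
        tracr_prefix=prefixes, expected_tracrs=expected,
        construct_ids=library.construct_ids,
        min_disambiguating_k=min_k,
    )


@dataclass
class ReadAssignment:
    construct_id: str | None
    crRNA_match: tuple[bool, bool]
    tracr_match: tuple[bool, bool]
    recombined: bool

    @property
    def mapped(self) -> bool:
        return self.construct_id is not None


def _locate(read: str, anchor: str, spacer_len: int, k: int,
            max_stagger: int = MAX_STAGGER) -> tuple[str, str] | None:
    """Scan stagger offsets for the anchor; return (spacer, tracr_prefix_obs)."""
    la = len(anchor)
    for off in range(max_stagger + 1):
        if read[off:off + la] == anchor:
            start = off + la
            spacer = read[start:start + spacer_len]
            tr = read[start + spacer_len:start + spacer_len + k]
            if len(spacer) == spacer_len and len(tr) == k:
                return spacer, tr
            return None
    return None


def _match_spacer(spacer: str, lookup: dict[str, set[str]],
                  max_mismatch: int) -> str | None:
    if spacer in lookup:
        return spacer
    if max_mismatch > 0:
        best, best_d = None, max_mismatch + 1
        for cand in lookup:
            d = hamming(spacer, cand)
            if d < best_d:
                best, best_d = cand, d
        if best is not None and best_d <= max_mismatch:
            return best
    return None


def assign_read_pair(read1: str, read2: str, index: ReferenceIndex,
                     max_mismatch: int = 0,
                     tracr_max_mismatch: int = 1) -> ReadAssignment:
    """Resolve one read pair to a construct and flag scaffold mismatches.

    The construct is resolved from the crRNA pair alone; each position's
    scaffold prefix is then compared against the construct's expected
    tracrRNA (allowing tracr_max_mismatch substitutions, default 1 — the
    scaffold set is divergent enough that one error cannot flip identity).
    """
    loc1 = _locate(read1, index.left_anchor, index.spacer_len, index.tracr_k)
    loc2 = _locate(reverse_complement(read2), index.right_anchor,
                   index.spacer_len, index.tracr_k)
    if loc1 is None or loc2 is None:
        return ReadAssignment(None, (loc1 is not None, loc2 is not None),
                              (False, False), False)

    s1 = _match_spacer(loc1[0], index.left_spacers, max_mismatch)
    s2 = _match_spacer(loc2[0], index.right_spacers, max_mismatch)
    cr_match = (s1 is not None, s2 is not None)
    if s1 is None or s2 is None:
        return ReadAssignment(None, cr_match, (False, False), False)
    cid = index.pair_lookup.get((s1, s2))
    if cid is None:
        return ReadAssignment(None, cr_match, (False, False), False)

    exp_l, exp_r = index.expected_tracrs[cid]
    tr_l_ok = hamming(loc1[1], index.tracr_prefix[exp_l]) <= tracr_max_mismatch
    tr_r_ok = hamming(loc2[1], index.tracr_prefix[exp_r]) <= tracr_max_mismatch
    recombined = not (tr_l_ok and tr_r_ok)
    return ReadAssignment(cid, cr_match, (tr_l_ok, tr_r_ok), recombined)


def count_reads(assignments: Iterable[ReadAssignment],
                construct_ids: list[str]) -> tuple[pd.Series, pd.Series, dict]:
    """Tally assignments at crRNA and sgRNA resolution.

    crRNA-level count: reads whose crRNA pair resolves the construct.
    sgRNA-level count: the subset whose scaffolds also both match.
    Returns (crRNA counts, sgRNA counts, stats dict); conservation holds:
    mapped + unmapped = total.
    """
    cr = dict.fromkeys(construct_ids, 0)
    sg = dict.fromkeys(construct_ids, 0)
    total = mapped = recombined = 0
    for a in assignments:
        total += 1
        if not a.mapped:
            continue
        mapped += 1
        cr[a.construct_id] += 1
        if not a.recombined:
            sg[a.construct_id] += 1
        else:
            recombined += 1
    stats = {"total": total, "mapped": mapped, "recombined": recombined,
             "unmapped": total - mapped}
    idx = pd.Index(construct_ids, name="construct_id")
    return (pd.Series(cr, name="crRNA").reindex(idx),
            pd.Series(sg, name="sgRNA").reindex(idx), stats)


def recombination_rate(crRNA_counts: pd.Series, sgRNA_counts: pd.Series,
                       min_reads: int = 30) -> tuple[pd.Series, float]:
    """Per-construct and library-level recombination rate.

    rate = 1 - sum(sgRNA) / sum(crRNA). Per-construct rates are NaN below
    min_reads crRNA-level reads and are excluded from interpretation; the
    library-level rate pools all reads. NaN if no reads mapped at all.
    """
    if ((sgRNA_counts > crRNA_counts)).any():
        raise ValueError("sgRNA counts exceed crRNA counts")
    cr_total = float(crRNA_counts.sum())
    library_rate = 1.0 - float(sgRNA_counts.sum()) / cr_total if cr_total > 0 else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        per = 1.0 - sgRNA_counts / crRNA_counts
    per = per.where(crRNA_counts >= min_reads)
    return per, library_rate


def _fastq_reads(path) -> Iterator[str]:
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip()


def map_fastq(r1_path, r2_path, index: ReferenceIndex,
              max_mismatch: int = 0,
              tracr_max_mismatch: int = 1) -> tuple[pd.Series, pd.Series, dict]:
    """Stream a FASTQ pair through the assigner and return count matrices."""
    pairs = zip(_fastq_reads(r1_path), _fastq_reads(r2_path))
    assignments = (assign_read_pair(r1, r2, index, max_mismatch, tracr_max_mismatch)
                   for r1, r2 in pairs)
    return count_reads(assignments, index.construct_ids)


def write_count_outputs(prefix: str, cr: pd.Series, sg: pd.Series, stats: dict) -> None:
    cr.rename_axis("construct_id").to_frame("count").to_csv(f"{prefix}.crRNA.tsv", sep="\t")
    sg.rename_axis("construct_id").to_frame("count").to_csv(f"{prefix}.sgRNA.tsv", sep="\t")
    with open(f"{prefix}.stats.json", "w") as fh:
        json.dump(stats, fh, indent=2)
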