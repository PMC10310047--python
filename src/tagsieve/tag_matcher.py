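"""Matching the non-redundant tag set against a protein database.

The search runs in three stages:

1. k-mer index lookup of the canonicalized tag sequence (I/L-equivalent
   substring search);
2. mass-gap resolution — extend the tag leftward/rightward one residue at a
   time until the accumulated monoisotopic flank mass (fixed modifications
   always applied, any admissible subset of variable modifications branched)
   explains the N-/C-terminal gap within the tolerance;
3. enzymatic cleavage validation of the candidate peptide.

A protein accumulates every spectrum of every tag for which it holds at
least one cleavage-valid peptide.  The computation is a pure function of
(database, tag set, parameters): partitioning the tag set into chunks and/or
processing chunks on several threads merges by set union and cannot change
the result.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .chem import ACETYL, CARBAMIDOMETHYL, MONOISOTOPIC, OXIDATION
from .sequence_db import ProteinRecord
from .tag_store import SequenceTag, SpectrumKey, canonicalize_seq

logger = logging.getLogger(__name__)

#: Pseudo-residue target for modifications of the protein N-terminus.
PROTEIN_NTERM = "protein-N-terminus"

#: protein accession -> sample -> set of spectra explaining it.
SpectralCounts = Dict[str, Dict[str, Set[SpectrumKey]]]


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed or variable mass modification.

    ``target`` is a residue letter or :data:`PROTEIN_NTERM`.  Fixed
    modifications apply unconditionally to every instance of the target;
    variable modifications branch (present/absent) per instance.  Deltas are
    assumed positive (required for the monotone search-pruning bound).
    """

    name: str
    target: str
    delta: float
    mode: str  # "fixed" | "variable"


def default_modifications() -> List[ModificationSpec]:
    return [
        ModificationSpec("Carbamidomethylation of C", "C", CARBAMIDOMETHYL, "fixed"),
        ModificationSpec("Oxidation of M", "M", OXIDATION, "variable"),
        ModificationSpec("Acetylation of protein N-term", PROTEIN_NTERM, ACETYL, "variable"),
    ]


@dataclass
class MatchParams:
    """Search settings; defaults mirror the benchmarking configuration
    (0.02 Da tolerance, carbamidomethyl C fixed, oxidation M and protein
    N-terminal acetylation variable, cleavage after all K/R with up to two
    missed cleavages)."""

    gap_tolerance: float = 0.02
    modifications: List[ModificationSpec] = field(default_factory=default_modifications)
    cleavage_rule: str = "trypsin-all-KR"
    max_missed_cleavages: int = 2
    il_equivalent: bool = True
    n_term_offset: float = 0.0
    c_term_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_tolerance <= 0:
            raise ValueError("gap_tolerance must be > 0")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.cleavage_rule != "trypsin-all-KR":
            raise ValueError(f"unsupported cleavage rule: {self.cleavage_rule!r}")

    @property
    def fixed_deltas(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for m in self.modifications:
            if m.mode == "fixed" and m.target != PROTEIN_NTERM:
                out[m.target] = out.get(m.target, 0.0) + m.delta
        return out

    @property
    def variable_residue(self) -> Dict[str, List[ModificationSpec]]:
        out: Dict[str, List[ModificationSpec]] = {}
        for m in self.modifications:
            if m.mode == "variable" and m.target != PROTEIN_NTERM:
                out.setdefault(m.target, []).append(m)
        return out

    @property
    def variable_nterm(self) -> List[ModificationSpec]:
        return [m for m in self.modifications
                if m.mode == "variable" and m.target == PROTEIN_NTERM]


@dataclass(frozen=True)
class PeptideMatch:
    """A cleavage-candidate peptide explaining one tag occurrence.

    Coordinates are 0-based half-open within the protein.  ``mod_assignment``
    records one witness set of variable modifications (position, spec) that
    satisfies the gaps; fixed modifications are implied.  A peptide is
    reported once per (protein, pep_start, pep_end) even if several
    modification assignments fit.
    """

    accession: str
    pep_start: int
    pep_end: int
    peptide: str
    tag: SequenceTag
    tag_offset: int
    mod_assignment: frozenset


class TagIndex:
    """Exact occurrence index of canonicalized k-mers over a database."""

    def __init__(self, records: Sequence[ProteinRecord], k: int,
                 il_equivalent: bool = True) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.records = list(records)
        self.k = k
        self.il_equivalent = il_equivalent
        index: Dict[str, List[Tuple[int, int]]] = {}
        for rec_idx, rec in enumerate(self.records):
            canon = canonicalize_seq(rec.sequence, il_equivalent)
            for pos in range(len(canon) - k + 1):
                index.setdefault(canon[pos:pos + k], []).append((rec_idx, pos))
        self._index = index

    def lookup(self, kmer: str) -> List[Tuple[int, int]]:
        """All (record index, position) occurrences of a canonical k-mer."""
        return self._index.get(canonicalize_seq(kmer, self.il_equivalent), [])


def build_index(records: Sequence[ProteinRecord], params: MatchParams,
                k: int = 4) -> TagIndex:
    return TagIndex(records, k=k, il_equivalent=params.il_equivalent)


def _flank_extensions(
    seq: str,
    anchor: int,
    gap: float,
    params: MatchParams,
    leftward: bool,
) -> Dict[int, Tuple[Tuple[int, ModificationSpec], ...]]:
    """Enumerate flank boundaries whose mass explains ``gap``.

    For the left flank the boundary is the peptide start s (flank is
    ``seq[s:anchor]``); for the right flank it is the peptide end e (flank is
    ``seq[anchor:e]``).  Returns boundary → one witness tuple of variable
    modifications.  Branches through a residue with no defined mass are
    abandoned; branches whose accumulated mass exceeds gap + tolerance are
    pruned (residue and modification masses are positive, so the mass is
    monotone in extension length).
    """
    tol = params.gap_tolerance
    gap = gap - (params.n_term_offset if leftward else params.c_term_offset)
    fixed = params.fixed_deltas
    var_res = params.variable_residue
    var_nterm = params.variable_nterm
    results: Dict[int, Tuple[Tuple[int, ModificationSpec], ...]] = {}
    stack: List[Tuple[int, float, Tuple[Tuple[int, ModificationSpec], ...]]] = [
        (anchor, 0.0, ())
    ]
    while stack:
        pos, acc, mods = stack.pop()
        if abs(acc - gap) <= tol:
            results.setdefault(pos, mods)
        if leftward and pos == 0:
            # Protein N-terminal variable mods become admissible exactly when
            # the extension reaches residue 0 (including an empty flank).
            for spec in var_nterm:
                if abs(acc + spec.delta - gap) <= tol:
                    results.setdefault(pos, mods + ((0, spec),))
            continue
        if leftward:
            res_pos = pos - 1
        else:
            if pos == len(seq):
                continue
            res_pos = pos
        residue = seq[res_pos]
        mono = MONOISOTOPIC.get(residue)
        if mono is None:
            continue  # undefined mass: abandon this branch
        base = acc + mono + fixed.get(residue, 0.0)
        new_pos = pos - 1 if leftward else pos + 1
        if base - tol <= gap:
            stack.append((new_pos, base, mods))
        for spec in var_res.get(residue, ()):  # e.g. oxidation per M
            modded = base + spec.delta
            if modded - tol <= gap:
                stack.append((new_pos, modded, mods + ((res_pos, spec),)))
    return results


def resolve_gaps(record: ProteinRecord, occurrence_position: int,
                 tag: SequenceTag, params: MatchParams) -> List[PeptideMatch]:
    """All peptide extensions of a tag occurrence satisfying both gaps.

    The tag sequence must occur at ``occurrence_position`` (under I/L
    canonicalization).  An n_gap within tolerance of zero means the peptide
    starts at the tag; symmetrically for the C side.  Cleavage validity is
    *not* checked here (see :func:`validate_cleavage`).
    """
    seq = record.sequence
    k = len(tag.tag_seq)
    lefts = _flank_extensions(seq, occurrence_position, tag.n_gap, params, leftward=True)
    if not lefts:
        return []
    rights = _flank_extensions(seq, occurrence_position + k, tag.c_gap, params,
                               leftward=False)
    matches = []
    for s in sorted(lefts):
        for e in sorted(rights):
            matches.append(PeptideMatch(
                accession=record.accession,
                pep_start=s,
                pep_end=e,
                peptide=seq[s:e],
                tag=tag,
                tag_offset=occurrence_position - s,
                mod_assignment=frozenset(lefts[s] + rights[e]),
            ))
    return matches


def validate_cleavage(record: ProteinRecord, pep_start: int, pep_end: int,
                      params: MatchParams) -> bool:
    """Tryptic cleavage check: cleavage after all Lys or Arg.

    True iff the peptide is preceded by K/R (or starts the protein), ends in
    K/R (or ends the protein), and contains at most ``max_missed_cleavages``
    internal K/R (positions other than the last residue).
    """
    seq = record.sequence
    if not (0 <= pep_start < pep_end <= len(seq)):
        raise ValueError("peptide coordinates out of range")
    sites = "KR"
    if pep_start != 0 and seq[pep_start - 1] not in sites:
        return False
    if pep_end != len(seq) and seq[pep_end - 1] not in sites:
        return False
    missed = sum(1 for ch in seq[pep_start:pep_end - 1] if ch in sites)
    return missed <= params.max_missed_cleavages


def _process_chunk(
    index: TagIndex,
    chunk: Sequence[Tuple[SequenceTag, Set[SpectrumKey]]],
    params: MatchParams,
) -> Tuple[SpectralCounts, List[PeptideMatch]]:
    counts: SpectralCounts = {}
    matches: List[PeptideMatch] = []
    for tag, spectra in chunk:
        hit_accessions = set()
        for rec_idx, pos in index.lookup(tag.tag_seq):
            rec = index.records[rec_idx]
            candidates = resolve_gaps(rec, pos, tag, params)
            valid = [m for m in candidates
                     if validate_cleavage(rec, m.pep_start, m.pep_end, params)]
            if not valid:
                continue
            matches.extend(valid)
            hit_accessions.add(rec.accession)
        for acc in hit_accessions:
            per_sample = counts.setdefault(acc, {})
            for sk in spectra:
                per_sample.setdefault(sk.sample, set()).add(sk)
    return counts, matches


def merge_counts(into: SpectralCounts, other: SpectralCounts) -> SpectralCounts:
    """Set-union merge; order-independent by construction."""
    for acc, per_sample in other.items():
        dst = into.setdefault(acc, {})
        for sample, spectra in per_sample.items():
            dst.setdefault(sample, set()).update(spectra)
    return into


def match_tags(
    index: TagIndex,
    tags: Mapping[SequenceTag, Set[SpectrumKey]],
    params: MatchParams,
    chunk_size: Optional[int] = None,
    threads: int = 1,
) -> Tuple[SpectralCounts, List[PeptideMatch]]:
    """Match the non-redundant tag set against the indexed database.

    Returns (SpectralCounts, PeptideMatch list).  A protein accumulates every
    spectrum of every tag for which it has at least one cleavage-valid
    peptide; spectra of a tag matched by several proteins are credited to all
    of them (non-unique spectra are shared).  Output is identical for any
    chunk size and thread count.
    """
    items = sorted(
        tags.items(),
        key=lambda kv: (kv[0].tag_seq, kv[0].n_gap, kv[0].c_gap),
    )
    for tag, _ in items:
        if len(tag.tag_seq) != index.k:
            raise ValueError(
                f"tag length {len(tag.tag_seq)} does not match index k={index.k}"
            )
    if chunk_size is None or chunk_size <= 0:
        chunk_size = max(1, len(items))
    chunks = [items[i:i + chunk_size] for i in range(0, len(items), chunk_size)]

    counts: SpectralCounts = {}
    matches: List[PeptideMatch] = []
    if threads > 1 and len(chunks) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(
                lambda ch: _process_chunk(index, ch, params), chunks))
    else:
        results = [_process_chunk(index, ch, params) for ch in chunks]
    for chunk_counts, chunk_matches in results:
        merge_counts(counts, chunk_counts)
        matches.extend(chunk_matches)
    matches.sort(key=lambda m: (m.accession, m.pep_start, m.pep_end,
                                m.tag.tag_seq, m.tag.n_gap, m.tag.c_gap))
    return counts, matches
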