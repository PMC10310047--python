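"""Independent oracles and random-instance generators for the test suite.

The matcher oracle enumerates every substring window, every flank extension
and every variable-modification subset exhaustively, recomputing flank
masses from scratch with math.fsum — sharing only the residue-mass table
with the implementation.  The ranking oracle recomputes NSAF/probabilities
with numpy arrays and filters with "retained-above" predecessor semantics
(the implementation walks "all-above"), so agreement is a real cross-check.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np

from tagsieve.chem import MONOISOTOPIC
from tagsieve.sequence_db import ProteinRecord
from tagsieve.tag_matcher import MatchParams, PROTEIN_NTERM
from tagsieve.tag_store import SequenceTag, SpectrumKey, canonicalize_seq

AA20 = sorted(MONOISOTOPIC)


# ---------------------------------------------------------------------------
# brute-force tag matcher


def _flank_mass_options(seq: str, params: MatchParams, at_nterm: bool) -> List[float]:
    """Every achievable mass of a flank: fixed mods always, each variable
    residue mod independently present/absent, N-terminal mods optionally
    when the flank starts at protein position 0.  Empty list if the flank
    contains a residue with no defined mass."""
    fixed = params.fixed_deltas
    var_res = params.variable_residue
    base_parts: List[float] = []
    optional: List[float] = []
    for i, ch in enumerate(seq):
        if ch not in MONOISOTOPIC:
            return []
        base_parts.append(MONOISOTOPIC[ch] + fixed.get(ch, 0.0))
        for spec in var_res.get(ch, ()):
            optional.append(spec.delta)
    if at_nterm:
        for spec in params.variable_nterm:
            optional.append(spec.delta)
    base = math.fsum(base_parts)
    masses = []
    for picks in product((0, 1), repeat=len(optional)):
        masses.append(base + math.fsum(d for d, p in zip(optional, picks) if p))
    return masses


def _cleavage_ok(seq: str, s: int, e: int, max_missed: int) -> bool:
    if s != 0 and seq[s - 1] not in "KR":
        return False
    if e != len(seq) and seq[e - 1] not in "KR":
        return False
    return sum(ch in "KR" for ch in seq[s:e - 1]) <= max_missed


def oracle_match(
    records: Sequence[ProteinRecord],
    tags: Mapping[SequenceTag, Set[SpectrumKey]],
    params: MatchParams,
) -> Tuple[Dict[str, Dict[str, Set[SpectrumKey]]], Set[Tuple]]:
    """Exhaustive reference for match_tags.

    Returns (SpectralCounts, set of (accession, pep_start, pep_end, tag))
    over cleavage-valid peptides.
    """
    tol = params.gap_tolerance
    counts: Dict[str, Dict[str, Set[SpectrumKey]]] = {}
    peptides: Set[Tuple] = set()
    for tag, spectra in tags.items():
        k = len(tag.tag_seq)
        canon_tag = canonicalize_seq(tag.tag_seq, params.il_equivalent)
        for rec in records:
            seq = rec.sequence
            canon_seq = canonicalize_seq(seq, params.il_equivalent)
            hit = False
            for t in range(len(seq) - k + 1):
                if canon_seq[t:t + k] != canon_tag:
                    continue
                lefts = []
                for s in range(t, -1, -1):
                    opts = _flank_mass_options(seq[s:t], params, at_nterm=(s == 0))
                    if not opts:
                        break  # undefined-mass residue stays in longer flanks
                    if any(abs(m - tag.n_gap) <= tol for m in opts):
                        lefts.append(s)
                    if min(opts) - tol > tag.n_gap:
                        break  # fixed-only mass is monotone in flank length
                rights = []
                for e in range(t + k, len(seq) + 1):
                    opts = _flank_mass_options(seq[t + k:e], params, at_nterm=False)
                    if not opts:
                        break
                    if any(abs(m - tag.c_gap) <= tol for m in opts):
                        rights.append(e)
                    if min(opts) - tol > tag.c_gap:
                        break
                for s in lefts:
                    for e in rights:
                        if _cleavage_ok(seq, s, e, params.max_missed_cleavages):
                            peptides.add((rec.accession, s, e, tag))
                            hit = True
            if hit:
                per = counts.setdefault(rec.accession, {})
                for sk in spectra:
                    per.setdefault(sk.sample, set()).add(sk)
    return counts, peptides


# ---------------------------------------------------------------------------
# random instances for the matcher oracle


def random_matcher_instance(rng: np.random.Generator,
                            max_proteins: int = 20,
                            max_len: int = 60,
                            n_tags: int = 8,
                            tag_length: int = 4):
    """Random small database plus a mix of true and decoy tags.

    True tags are read from real windows with exact (or slightly jittered)
    flank masses including random variable-mod choices; decoys are random
    letters with random gaps.  Some proteins carry ambiguity letters to
    exercise the undefined-mass branch.
    """
    params = MatchParams()
    n_prot = int(rng.integers(3, max_proteins + 1))
    letters = AA20 + ["X"]  # X: no defined mass
    weights = np.array([1.0] * len(AA20) + [0.4])
    weights /= weights.sum()
    records = []
    for i in range(n_prot):
        length = int(rng.integers(tag_length + 2, max_len + 1))
        seq = "".join(rng.choice(letters, size=length, p=weights))
        records.append(ProteinRecord(accession=f"P{i:02d}", header=f"P{i:02d}",
                                     sequence=seq))
    tags: Dict[SequenceTag, Set[SpectrumKey]] = {}
    spectrum_no = 0
    while len(tags) < n_tags:
        spectrum_no += 1
        spectra = {SpectrumKey("s1", f"sp{spectrum_no}{j}")
                   for j in range(int(rng.integers(1, 3)))}
        if rng.random() < 0.5:
            # true tag from a real window
            rec = records[int(rng.integers(0, len(records)))]
            seq = rec.sequence
            if len(seq) < tag_length:
                continue
            t = int(rng.integers(0, len(seq) - tag_length + 1))
            window = seq[t:t + tag_length]
            if any(ch not in MONOISOTOPIC for ch in window):
                continue
            s = int(rng.integers(0, t + 1))
            e = int(rng.integers(t + tag_length, len(seq) + 1))
            n_opts = _flank_mass_options(seq[s:t], params, at_nterm=(s == 0))
            c_opts = _flank_mass_options(seq[t + tag_length:e], params,
                                         at_nterm=False)
            if not n_opts or not c_opts:
                continue
            n_gap = float(rng.choice(n_opts))
            c_gap = float(rng.choice(c_opts))
            if rng.random() < 0.3:  # jitter near the tolerance boundary
                n_gap += float(rng.uniform(-0.03, 0.03))
                c_gap += float(rng.uniform(-0.03, 0.03))
            tag = SequenceTag(max(0.0, n_gap), window, max(0.0, c_gap))
        else:
            window = "".join(rng.choice(AA20, size=tag_length))
            tag = SequenceTag(float(rng.uniform(0, 300)), window,
                              float(rng.uniform(0, 300)))
        tags.setdefault(tag, set()).update(spectra)
    return records, tags, params


# ---------------------------------------------------------------------------
# ranking oracle and random instances


def random_counts_instance(rng: np.random.Generator,
                           max_proteins: int = 15,
                           max_spectra: int = 30,
                           n_samples: int = 2,
                           n_organisms: int = 3):
    """Random SpectralCounts with lengths and organisms, including exact
    duplicate spectrum sets to exercise isoform collapse."""
    n_prot = int(rng.integers(2, max_proteins + 1))
    universe = [SpectrumKey(f"s{1 + i % n_samples}", f"sp{i:03d}")
                for i in range(int(rng.integers(2, max_spectra + 1)))]
    counts = {}
    lengths = {}
    organisms = {}
    for i in range(n_prot):
        acc = f"P{i:02d}"
        size = int(rng.integers(1, max(2, len(universe) // 2)))
        picks = rng.choice(len(universe), size=min(size, len(universe)),
                           replace=False)
        spectra = {universe[j] for j in picks}
        per = {}
        for sk in spectra:
            per.setdefault(sk.sample, set()).add(sk)
        counts[acc] = per
        lengths[acc] = int(rng.integers(50, 500))
        organisms[acc] = f"Org_{int(rng.integers(1, n_organisms + 1))}"
    # isoform pair: duplicate spectrum set, length + 1
    if rng.random() < 0.7 and counts:
        base = f"P{int(rng.integers(0, n_prot)):02d}"
        twin = base + "b"
        counts[twin] = {s: set(v) for s, v in counts[base].items()}
        lengths[twin] = lengths[base] + 1
        organisms[twin] = organisms[base]
    return counts, lengths, organisms


def oracle_two_pass_retained(counts, lengths, organisms):
    """Independent two-pass filter: numpy NSAF arithmetic and a
    retained-above greedy scan (rescanning the retained list each step)."""
    accs = sorted(counts)
    samples = sorted({s for per in counts.values() for s in per})
    saf = np.array([[len(counts[a].get(s, ())) / lengths[a] for s in samples]
                    for a in accs])
    totals = saf.sum(axis=0)
    nsaf = np.divide(saf, totals, out=np.zeros_like(saf), where=totals > 0)
    nsaf_sum = nsaf.sum(axis=1)
    p_protein = nsaf_sum / nsaf_sum.sum()

    def spectra_of(a):
        out = set()
        for v in counts[a].values():
            out |= v
        return out

    def greedy(order):
        retained = []
        for a in order:
            seen = set()
            for r in retained:  # retained-above semantics
                seen |= spectra_of(r)
            if spectra_of(a) - seen:
                retained.append(a)
        return retained

    def sort_order(primary):
        key = {a: (-primary[i], -nsaf_sum[i], lengths[a], a)
               for i, a in enumerate(accs)}
        return sorted(accs, key=lambda a: key[a])

    pass1 = greedy(sort_order(p_protein))
    org_sums: Dict[str, float] = {}
    idx = {a: i for i, a in enumerate(accs)}
    for a in pass1:
        org_sums[organisms[a]] = org_sums.get(organisms[a], 0.0) + nsaf_sum[idx[a]]
    total = sum(org_sums.values())
    p_org = {o: v / total for o, v in org_sums.items()}
    joint = np.array([p_org.get(organisms[a], 0.0) * p_protein[i]
                      for i, a in enumerate(accs)])
    final = greedy(sort_order(joint))
    return pass1, p_org, final
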