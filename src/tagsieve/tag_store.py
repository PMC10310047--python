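"""Per-spectrum de novo sequence tags and the non-redundant tag set.

A tag is an (N-gap mass, amino-acid string, C-gap mass) triple observed in
one MS/MS spectrum.  Identical tags across spectra are combined into a single
non-redundant list; the back-map from each canonical tag to the spectra that
produced it drives spectral counting later.

Canonicalization:

* I/L are isobaric and indistinguishable by fragment mass, so tag sequences
  are canonicalized with I→L for identity and matching.
* Gap masses are rounded to 4 decimal places for tag identity; the first
  observed full-precision values are retained for matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Dict, Iterable, List, Set, Tuple, Union

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MAX_TAGS_PER_SPECTRUM = 5
GAP_CANON_DECIMALS = 4

REQUIRED_COLUMNS = ["sample", "spectrum_id", "n_gap", "tag_seq", "c_gap", "rank"]

_IL_TABLE = str.maketrans("I", "L")


def canonicalize_seq(seq: str, il_equivalent: bool = True) -> str:
    """Canonical form of a tag / k-mer sequence (I→L when enabled)."""
    seq = seq.upper()
    return seq.translate(_IL_TABLE) if il_equivalent else seq


@dataclass(frozen=True, order=True)
class SpectrumKey:
    sample: str
    spectrum_id: str


@dataclass(frozen=True)
class SequenceTag:
    """An (n_gap, tag_seq, c_gap) triple; gaps are neutral masses in Da."""

    n_gap: float
    tag_seq: str
    c_gap: float

    def canonical_key(self, il_equivalent: bool = True) -> Tuple[str, float, float]:
        return (
            canonicalize_seq(self.tag_seq, il_equivalent),
            round(self.n_gap, GAP_CANON_DECIMALS),
            round(self.c_gap, GAP_CANON_DECIMALS),
        )


@dataclass(frozen=True)
class TagObservation:
    spectrum: SpectrumKey
    tag: SequenceTag
    rank: int


class TagStore:
    """Observations of tags in spectra, deduplicated on full identity."""

    def __init__(self, max_rank: int = DEFAULT_MAX_TAGS_PER_SPECTRUM,
                 il_equivalent: bool = True) -> None:
        self.max_rank = max_rank
        self.il_equivalent = il_equivalent
        self._observations: Dict[TagObservation, None] = {}

    def add(self, obs: TagObservation) -> None:
        if obs.rank > self.max_rank:
            logger.warning(
                "dropping tag observation with rank %d > %d for spectrum %s/%s",
                obs.rank, self.max_rank, obs.spectrum.sample, obs.spectrum.spectrum_id,
            )
            return
        self._observations.setdefault(obs, None)

    @property
    def observations(self) -> List[TagObservation]:
        return list(self._observations)

    def spectra(self) -> Set[SpectrumKey]:
        return {obs.spectrum for obs in self._observations}

    def __len__(self) -> int:
        return len(self._observations)

    def distinct_tags(self) -> Dict[SequenceTag, Set[SpectrumKey]]:
        """Non-redundant tag set with the tag→spectra back-map.

        Keys are representative SequenceTags (first observed full-precision
        gaps); identity follows the canonicalization rules above.  Every
        observation is reachable through exactly one canonical tag.
        """
        reps: Dict[Tuple[str, float, float], SequenceTag] = {}
        back: Dict[SequenceTag, Set[SpectrumKey]] = {}
        for obs in self._observations:
            key = obs.tag.canonical_key(self.il_equivalent)
            rep = reps.get(key)
            if rep is None:
                rep = obs.tag
                reps[key] = rep
                back[rep] = set()
            back[rep].add(obs.spectrum)
        return back


def load_tags(
    source: Union[str, Path, IO[str]],
    max_rank: int = DEFAULT_MAX_TAGS_PER_SPECTRUM,
    il_equivalent: bool = True,
) -> TagStore:
    """Load a tab-separated tag table into a TagStore.

    Required columns: sample, spectrum_id, n_gap, tag_seq, c_gap, rank (header
    row required).  Gap masses must parse as non-negative reals; offending
    rows are reported with their 1-based file line number.  Observations with
    rank beyond ``max_rank`` are dropped with a warning.
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed tag table: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tag table missing required columns: {missing}")

    store = TagStore(max_rank=max_rank, il_equivalent=il_equivalent)
    if df.empty:
        return store

    for col in ("n_gap", "c_gap"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        if bad.any():
            line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"tag table line {line}: column {col!r} is not a "
                f"non-negative mass ({df.loc[df.index[bad][0], col]!r})"
            )
        df[col] = vals
    ranks = pd.to_numeric(df["rank"], errors="coerce")
    if ranks.isna().any() or (ranks < 1).any():
        bad = ranks.isna() | (ranks < 1)
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"tag table line {line}: rank must be an integer >= 1")
    df["rank"] = ranks.astype(int)

    for row in df.itertuples(index=False):
        store.add(TagObservation(
            spectrum=SpectrumKey(sample=str(row.sample), spectrum_id=str(row.spectrum_id)),
            tag=SequenceTag(n_gap=float(row.n_gap), tag_seq=str(row.tag_seq),
                            c_gap=float(row.c_gap)),
            rank=int(row.rank),
        ))
    return store


def write_tags(observations: Iterable[TagObservation],
               dest: Union[str, Path, IO[str]]) -> None:
    """Write observations back out as a tab-separated tag table."""
    rows = [
        {
            "sample": o.spectrum.sample,
            "spectrum_id": o.spectrum.spectrum_id,
            "n_gap": repr(o.tag.n_gap),
            "tag_seq": o.tag.tag_seq,
            "c_gap": repr(o.tag.c_gap),
            "rank": o.rank,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(dest, sep="\t", index=False)
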