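"""Parsing of spoken-observation transcripts and positive-control detection.

Each transcript line is one spoken row observation in the dialect

    "<participant>, <row>. <free text>"

where the participant is a NATO code name stated at the start of the
recording and the row number may carry thousands separators as rendered
by the transcription ("Alpha, 1,641. Plants are flowering...").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Observation",
    "FieldLayout",
    "SynonymList",
    "ParseError",
    "parse_observation",
    "format_observation",
    "read_transcripts",
    "link_observations",
    "synonym_detection",
    "read_synonym_lists",
]

log = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)

# "<name>, <number>. <text>" — name is anything without a comma; the row
# number may contain "," or "_" thousands separators.
_HEADER_RE = re.compile(r"^\s*([^,.]+?)\s*,\s*([0-9][0-9,_]*)\s*\.\s*(.*)$", re.DOTALL)


class ParseError(ValueError):
    """A transcript line that does not follow the observation dialect."""


@dataclass(frozen=True)
class Observation:
    participant: str
    row: int
    text: str
    date: str | None = None  # ISO date if known

    def __post_init__(self):
        if self.row < 1:
            raise ValueError(f"row must be >= 1, got {self.row}")
        if not self.text.strip():
            raise ValueError("observation text is empty")


def parse_observation(line: str) -> Observation:
    """Parse one transcript line into an :class:`Observation`.

    Raises :class:`ParseError` identifying the offending line when the
    header is missing, the row is non-numeric, or the text is empty.
    """
    m = _HEADER_RE.match(line)
    if not m:
        raise ParseError(f"not an observation line (missing '<name>, <row>.' header): {line!r}")
    name, rowstr, text = m.groups()
    rowstr = rowstr.replace(",", "").replace("_", "")
    if not rowstr.isdigit():
        raise ParseError(f"non-numeric row number in line: {line!r}")
    text = text.strip()
    if not text:
        raise ParseError(f"empty observation text in line: {line!r}")
    return Observation(participant=name.strip(), row=int(rowstr), text=text)


def format_observation(obs: Observation, separators: bool = True) -> str:
    """Render an observation back into its one-line dialect."""
    row = f"{obs.row:,}" if separators else str(obs.row)
    return f"{obs.participant}, {row}. {obs.text}"


def read_transcripts(path: str | Path, on_error: str = "raise") -> pd.DataFrame:
    """Read a transcript file (UTF-8, one observation per line).

    ``on_error``: "raise" aborts on the first malformed line; "skip"
    drops malformed lines with a logged count.
    Returns a DataFrame with columns participant, row, text.
    """
    records, bad = [], 0
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                o = parse_observation(line.rstrip("\n"))
            except ParseError:
                if on_error == "raise":
                    raise ParseError(f"{path}:{i}: malformed observation line")
                bad += 1
                continue
            records.append((o.participant, o.row, o.text))
    if bad:
        log.warning("%s: skipped %d malformed lines", path, bad)
    return pd.DataFrame(records, columns=["participant", "row", "text"])


# ---------------------------------------------------------------------------
# Field layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldLayout:
    """Mapping of field row number -> (taxon, replicate, block label)."""

    table: pd.DataFrame  # columns: row, taxon, replicate, block

    def __post_init__(self):
        t = self.table
        required = {"row", "taxon", "replicate"}
        if missing := required - set(t.columns):
            raise ValueError(f"layout missing columns {sorted(missing)}")
        if t["row"].duplicated().any():
            dups = t.loc[t["row"].duplicated(), "row"].tolist()[:5]
            raise ValueError(f"duplicate row numbers in layout: {dups}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.table["taxon"].unique())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FieldLayout":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def link_observations(
    observations: pd.DataFrame, layout: FieldLayout
) -> tuple[pd.DataFrame, float]:
    """Attach taxon and replicate to observations via the field layout.

    Observations whose row is absent from the layout (e.g. rows for taxa
    outside the genotyped panel) are dropped and counted.  Returns the
    linked table and the retained fraction.
    """
    if len(layout) == 0:
        raise ValueError("empty field layout")
    cols = ["row", "taxon", "replicate"]
    if "block" in layout.table.columns:
        cols.append("block")
    merged = observations.merge(layout.table[cols], on="row", how="inner")
    retained = len(merged) / len(observations) if len(observations) else 1.0
    dropped = len(observations) - len(merged)
    if dropped:
        log.info("dropped %d observations with rows absent from layout", dropped)
    return merged, retained


# ---------------------------------------------------------------------------
# Positive-control synonym detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynonymList:
    """Synonyms for one positive-control accession from one thesaurus source."""

    accession: str
    source: str
    synonyms: tuple[str, ...]

    def __post_init__(self):
        if not self.synonyms:
            raise ValueError(f"empty synonym list for {self.accession}/{self.source}")
        # dedupe case-insensitively, preserving first spelling
        seen, uniq = set(), []
        for s in self.synonyms:
            k = s.lower()
            if k not in seen:
                seen.add(k)
                uniq.append(s)
        object.__setattr__(self, "synonyms", tuple(uniq))


def read_synonym_lists(path: str | Path) -> list[SynonymList]:
    """Read synonym lists from TSV with columns accession, source, synonym."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (acc, src), grp in df.groupby(["accession", "source"], sort=True):
        out.append(SynonymList(str(acc), str(src), tuple(grp["synonym"].astype(str))))
    return out


def _contains_synonym(text_tokens: tuple[str, ...], syn_tokens: tuple[str, ...]) -> bool:
    k = len(syn_tokens)
    return any(
        text_tokens[i : i + k] == syn_tokens
        for i in range(len(text_tokens) - k + 1)
    )


def synonym_detection(
    observations_by_accession: Mapping[str, Sequence[str]],
    synonym_lists: Iterable[SynonymList],
) -> pd.DataFrame:
    """Proportion of observations containing at least one synonym.

    For each (accession, source) pair: the fraction of that accession's
    observations containing >= 1 synonym, matched case-insensitively as
    whole words; multiword synonyms match as contiguous token sequences.
    """
    rows = []
    for sl in synonym_lists:
        try:
            texts = observations_by_accession[sl.accession]
        except KeyError:
            raise KeyError(f"no observations for accession {sl.accession!r}") from None
        if len(texts) == 0:
            raise ValueError(f"no observations for accession {sl.accession!r}")
        syn_tok = [tuple(_TOKEN_RE.findall(s.lower())) for s in sl.synonyms]
        n_hit = 0
        for t in texts:
            tt = tuple(_TOKEN_RE.findall(t.lower()))
            if any(_contains_synonym(tt, st) for st in syn_tok):
                n_hit += 1
        rows.append(
            {
                "accession": sl.accession,
                "source": sl.source,
                "n_synonyms": len(sl.synonyms),
                "n_observations": len(texts),
                "n_with_synonym": n_hit,
                "proportion": n_hit / len(texts),
            }
        )
    return pd.DataFrame(rows)
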