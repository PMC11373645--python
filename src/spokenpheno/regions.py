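"""Candidate regions around significant markers and their annotation.

A significant SNP defines a window of ± a halfwidth (default 300 kb,
justified by the LD-decay curve); gene models overlapping that window by
at least one base pair are collected as candidates, flagged against a
literature list of known height genes, compared across analyses, and
summarized by hormone-keyword GO term counts (auxin, brassinosteroid,
gibberellin — the hormones controlling plant stature).

Coordinates are 1-based inclusive (GFF3 convention); windows are
clipped at position 1.  Regions are never merged: each significant
marker yields its own region, and overlap is handled at comparison
time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assoc import AssociationResult

__all__ = [
    "GeneModel",
    "CandidateRegion",
    "read_gff3_genes",
    "read_go_map",
    "read_go_names",
    "read_literature_list",
    "collect_genes",
    "intersect_literature",
    "shared_regions",
    "go_keyword_counts",
    "HORMONE_KEYWORDS",
]

log = logging.getLogger(__name__)

HORMONE_KEYWORDS = ("auxin", "brassinosteroid", "gibberellin")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"bad coordinates for {self.gene_id}: [{self.start}, {self.end}]"
            )


@dataclass
class CandidateRegion:
    """±window interval around one significant marker, with its genes."""

    analysis: str
    marker: str
    chrom: str
    pos: int
    start: int
    end: int
    genes: tuple[str, ...]
    go_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    literature_hit: bool = False

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene models (feature type 'gene') from a GFF3 file.

    Returns a DataFrame (gene_id, chrom, start, end, name).  Uses
    gffutils so attribute quirks (ID prefixes like "gene:") are handled
    the standard way.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    recs = []
    for g in db.features_of_type("gene"):
        gid = g.id.removeprefix("gene:")
        name = g.attributes.get("Name", [gid])[0]
        recs.append((gid, str(g.seqid), int(g.start), int(g.end), name))
    return pd.DataFrame(recs, columns=["gene_id", "chrom", "start", "end", "name"])


def read_go_map(path: str | Path) -> pd.DataFrame:
    """gene -> GO ID map from TSV with columns gene_id, go_id."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_go_names(path: str | Path) -> dict[str, str]:
    """GO ID -> term name from TSV with columns go_id, name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["go_id"], df["name"]))


def read_literature_list(path: str | Path) -> list[str]:
    """One gene-model ID per line; blank lines and '#' comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out


def collect_genes(
    significant: AssociationResult | pd.DataFrame,
    annotation: pd.DataFrame,
    halfwidth: int = 300_000,
    analysis: str = "analysis",
    go_map: pd.DataFrame | None = None,
) -> list[CandidateRegion]:
    """Candidate regions: genes overlapping ±halfwidth of each significant SNP.

    A gene belongs to a region iff its [start, end] intersects the
    window [max(1, pos - halfwidth), pos + halfwidth] by >= 1 bp on the
    same chromosome.  Annotation chromosomes absent from the marker set
    are skipped with a warning.  ``go_map`` (gene_id, go_id) attaches GO
    IDs per gene when given.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    table = significant.significant() if isinstance(significant, AssociationResult) else significant
    ann = annotation.copy()
    ann["chrom"] = ann["chrom"].astype(str)
    marker_chroms = set(table["chrom"].astype(str))
    unknown = set(ann["chrom"]) - marker_chroms
    if unknown and not table.empty:
        warnings.warn(f"annotation chromosomes not in marker set skipped: {sorted(unknown)[:5]}")
    go_by_gene: dict[str, tuple[str, ...]] = {}
    if go_map is not None:
        go_by_gene = {
            g: tuple(sorted(set(grp["go_id"])))
            for g, grp in go_map.groupby("gene_id")
        }
    regions = []
    for rec in table.itertuples(index=False):
        chrom = str(rec.chrom)
        start = max(1, int(rec.pos) - halfwidth)
        end = int(rec.pos) + halfwidth
        sel = ann[(ann["chrom"] == chrom) & (ann["end"] >= start) & (ann["start"] <= end)]
        genes = tuple(dict.fromkeys(sel["gene_id"]))
        regions.append(
            CandidateRegion(
                analysis=analysis,
                marker=str(rec.marker),
                chrom=chrom,
                pos=int(rec.pos),
                start=start,
                end=end,
                genes=genes,
                go_terms={g: go_by_gene.get(g, ()) for g in genes},
            )
        )
    return regions


def intersect_literature(
    regions: Sequence[CandidateRegion], literature: Iterable[str]
) -> pd.DataFrame:
    """Flag regions containing at least one literature height gene.

    Mutates each region's ``literature_hit`` flag and returns a summary
    DataFrame (analysis, n_regions, n_with_literature_gene).
    """
    lit = set(literature)
    if not lit:
        warnings.warn("empty literature list; all flags false")
    for r in regions:
        r.literature_hit = bool(lit & set(r.genes))
    rows = []
    for analysis in dict.fromkeys(r.analysis for r in regions):
        sub = [r for r in regions if r.analysis == analysis]
        rows.append(
            {
                "analysis": analysis,
                "n_regions": len(sub),
                "n_with_literature_gene": sum(r.literature_hit for r in sub),
            }
        )
    return pd.DataFrame(rows)


def shared_regions(
    a: Sequence[CandidateRegion], b: Sequence[CandidateRegion]
) -> pd.DataFrame:
    """Pairs of regions from two analyses that overlap on a chromosome.

    A pair is shared iff same chromosome and overlapping windows; the
    same-marker flag marks identical marker positions.  Returns the pair
    table with counts derivable by the caller.
    """
    rows = []
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            if ra.start <= rb.end and rb.start <= ra.end:
                rows.append(
                    {
                        "marker_a": ra.marker,
                        "marker_b": rb.marker,
                        "chrom": ra.chrom,
                        "pos_a": ra.pos,
                        "pos_b": rb.pos,
                        "same_marker": ra.pos == rb.pos,
                    }
                )
    return pd.DataFrame(
        rows, columns=["marker_a", "marker_b", "chrom", "pos_a", "pos_b", "same_marker"]
    )


def go_keyword_counts(
    regions: Sequence[CandidateRegion],
    go_map: pd.DataFrame,
    term_names: Mapping[str, str],
    keywords: Sequence[str] = HORMONE_KEYWORDS,
    split_by_literature: bool = False,
) -> pd.DataFrame:
    """Hormone-keyword GO annotation counts among region genes.

    Counts distinct (gene, GO term) annotation pairs whose term name
    contains the keyword (case-insensitive substring), per analysis and
    keyword.  GO IDs without a known term name count as unannotated.
    With ``split_by_literature`` the count is split by the regions'
    literature flag (set by :func:`intersect_literature`).
    """
    go_by_gene = {
        g: tuple(sorted(set(grp["go_id"]))) for g, grp in go_map.groupby("gene_id")
    }
    rows = []
    for analysis in dict.fromkeys(r.analysis for r in regions):
        sub = [r for r in regions if r.analysis == analysis]
        groups = (
            {"literature": [r for r in sub if r.literature_hit],
             "this_study": [r for r in sub if not r.literature_hit]}
            if split_by_literature
            else {"all": sub}
        )
        for gname, regs in groups.items():
            pairs = set()
            for r in regs:
                for g in r.genes:
                    for go in r.go_terms.get(g) or go_by_gene.get(g, ()):
                        pairs.add((g, go))
            for kw in keywords:
                n = sum(
                    1
                    for g, go in pairs
                    if kw.lower() in term_names.get(go, "").lower()
                )
                rows.append(
                    {"analysis": analysis, "group": gname, "keyword": kw, "count": n}
                )
    return pd.DataFrame(rows)
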