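"""Stage orchestration: each stage reads TSV artifacts, writes TSV artifacts
plus a JSON run manifest, and can be chained end to end.

The stages mirror the analysis flow: simulate -> parse -> detect /
score-semantic / score-bins -> adjust -> gwas -> annotate -> compare.
Artifacts live in a single run directory; a stage that needs an
upstream artifact raises a :class:`StageDependencyError` naming the
stage to run first.  Reruns with the same config and seed are
bit-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjusted_means import fit_blue, fit_blup, fit_multinomial
from .assoc import bonferroni_threshold, compute_pcs, ld_decay, scan, select_window
from .genotypes import read_genotypes, write_dosage_tsv, write_vcf
from .phenoscore import (
    DEFAULT_QUERIES,
    HashedBowBackend,
    PhraseLexicon,
    default_lexicon,
    get_backend,
    retention_stats,
    score_transcripts_bins,
    score_transcripts_semantic,
)
from .regions import (
    collect_genes,
    go_keyword_counts,
    intersect_literature,
    read_gff3_genes,
    read_go_map,
    read_go_names,
    read_literature_list,
    shared_regions,
)
from .synthetic_data import (
    SimConfig,
    field_composition,
    generate_transcripts,
    layout_field,
    simulate_annotation,
    simulate_genotypes,
    simulate_go_annotations,
    simulate_literature_list,
    simulate_trait,
    write_gff3,
    write_transcripts,
)
from .transcripts import (
    FieldLayout,
    link_observations,
    read_synonym_lists,
    read_transcripts,
    synonym_detection,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Pipeline", "StageDependencyError", "STAGES"]

STAGES = (
    "simulate", "parse", "detect", "score-semantic", "score-bins",
    "adjust", "gwas", "annotate", "compare",
)


class StageDependencyError(FileNotFoundError):
    """An upstream artifact is missing; the message names the stage to run."""


@dataclass
class PipelineConfig:
    """Single flat configuration for all stages (YAML-loadable)."""

    outdir: str = "run"
    # input paths; None means "use the artifact the simulate stage wrote"
    transcripts: str | None = None
    layout: str | None = None
    genotypes: str | None = None
    annotation: str | None = None
    go_map: str | None = None
    go_names: str | None = None
    literature: str | None = None
    lexicon: str | None = None
    synonym_lists: str | None = None
    # method selectors
    method: str = "binned"  # measured | semantic | binned
    model: str = "blue"  # blue | blup | multinomial
    backend: str = "hashed-bow"
    queries: tuple[str, ...] = DEFAULT_QUERIES
    # scan parameters
    pcs: int = 3
    alpha: float = 0.05
    window: int = 300_000
    per_chromosome: bool = False
    window_r2: float = 0.2
    # simulation block
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def __post_init__(self):
        if self.method not in {"measured", "semantic", "binned"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.model not in {"blue", "blup", "multinomial"}:
            raise ValueError(f"unknown model {self.model!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim_raw = raw.pop("sim", {})
        seed = raw.get("seed", 0)
        sim_raw.setdefault("seed", seed)
        if "participants" in sim_raw:
            sim_raw["participants"] = tuple(sim_raw["participants"])
        if "noise_sentences" in sim_raw:
            sim_raw["noise_sentences"] = tuple(sim_raw["noise_sentences"])
        if "maf_range" in sim_raw:
            sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
        if "queries" in raw:
            raw["queries"] = tuple(raw["queries"])
        return cls(sim=SimConfig(**sim_raw), **raw)


class Pipeline:
    """Runs stages against one output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- plumbing ----------------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _require(self, name: str, stage: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise StageDependencyError(
                f"missing artifact {p}; run the '{stage}' stage first"
            )
        return p

    def _resolve(self, attr: str, artifact: str, stage: str) -> Path:
        configured = getattr(self.config, attr)
        if configured:
            p = Path(configured)
            if not p.exists():
                raise FileNotFoundError(f"configured {attr} path {p} does not exist")
            return p
        return self._require(artifact, stage)

    def _manifest(self, stage: str, inputs: Sequence[str], params: dict[str, Any],
                  counts: dict[str, int]) -> None:
        def _rel(p: str) -> str:
            # record run-dir artifacts by name so identical reruns in
            # different directories stay byte-identical
            p = Path(p)
            try:
                return str(p.relative_to(self.outdir))
            except ValueError:
                return p.name
        man = {
            "stage": stage,
            "package_version": __version__,
            "seed": self.config.seed,
            "inputs": sorted(_rel(i) for i in inputs),
            "parameters": params,
            "row_counts": counts,
        }
        with open(self._path(f"manifest_{stage.replace('-', '_')}.json"), "w") as fh:
            json.dump(man, fh, indent=2, sort_keys=True)
        log.info("stage %s: %s", stage, counts)

    def _lexicon(self) -> PhraseLexicon:
        if self.config.lexicon:
            return PhraseLexicon.from_tsv(self.config.lexicon)
        return default_lexicon()

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        """Generate the full synthetic study into the run directory."""
        sim = self.config.sim
        geno = simulate_genotypes(sim)
        n_special = sim.rows_per_rep - sim.n_taxa
        if n_special >= 65 and sim.rows_per_rep == 720:
            panel = geno.taxa[: sim.rows_per_rep - 65]
            taxa, blocks = field_composition(panel)
        else:
            if n_special < 0:
                raise ValueError("rows_per_rep smaller than n_taxa")
            taxa = list(geno.taxa) + [geno.taxa[i % len(geno.taxa)] for i in range(n_special)]
            blocks = None
        layout = layout_field(taxa, sim, blocks)
        trait = simulate_trait(geno, layout, sim)
        lex = self._lexicon()
        obs = generate_transcripts(layout, trait, lex, sim)
        write_transcripts(obs, self._path("transcripts.txt"))
        layout.to_tsv(self._path("layout.tsv"))
        write_dosage_tsv(geno, self._path("genotypes.tsv"))
        write_vcf(geno, self._path("genotypes.vcf"))
        trait.genetic.rename("genetic").rename_axis("taxon").reset_index().to_csv(
            self._path("truth_genetic.tsv"), sep="\t", index=False
        )
        trait.observations.to_csv(self._path("truth_observations.tsv"), sep="\t", index=False)
        trait.causal.to_csv(self._path("truth_causal.tsv"), sep="\t", index=False)
        ann = simulate_annotation(sim)
        write_gff3(ann, self._path("annotation.gff3"))
        go = simulate_go_annotations(ann, sim)
        go.to_csv(self._path("go_map.tsv"), sep="\t", index=False)
        from .synthetic_data import GO_TERMS
        pd.DataFrame(
            {"go_id": list(GO_TERMS), "name": list(GO_TERMS.values())}
        ).to_csv(self._path("go_names.tsv"), sep="\t", index=False)
        lit = simulate_literature_list(ann, trait.causal, sim)
        self._path("literature.txt").write_text("\n".join(lit) + "\n")
        lex.to_tsv(self._path("lexicon.tsv"))
        self._manifest(
            "simulate", [],
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(sim).items()},
            {"taxa": geno.n_taxa, "markers": geno.n_markers,
             "rows": len(layout), "observations": len(obs)},
        )

    def parse(self) -> pd.DataFrame:
        """Parse transcripts and link them to the field layout."""
        tpath = self._resolve("transcripts", "transcripts.txt", "simulate")
        lpath = self._resolve("layout", "layout.tsv", "simulate")
        obs = read_transcripts(tpath)
        layout = FieldLayout.from_tsv(lpath)
        linked, retained = link_observations(obs, layout)
        linked.to_csv(self._path("observations.tsv"), sep="\t", index=False)
        self._manifest(
            "parse", [tpath, lpath], {"retained_fraction": retained},
            {"observations": len(obs), "linked": len(linked)},
        )
        return linked

    def detect(self) -> pd.DataFrame:
        """Positive-control synonym-detection proportions."""
        if not self.config.synonym_lists:
            raise FileNotFoundError("detect stage needs config.synonym_lists (TSV path)")
        opath = self._require("observations.tsv", "parse")
        obs = pd.read_csv(opath, sep="\t")
        syn = read_synonym_lists(self.config.synonym_lists)
        by_acc = {
            acc: grp["text"].tolist() for acc, grp in obs.groupby("taxon")
        }
        table = synonym_detection(by_acc, [s for s in syn if s.accession in by_acc])
        table.to_csv(self._path("synonym_proportions.tsv"), sep="\t", index=False)
        self._manifest("detect", [opath, self.config.synonym_lists], {},
                       {"pairs": len(table)})
        return table

    def score_semantic(self) -> pd.DataFrame:
        opath = self._require("observations.tsv", "parse")
        obs = pd.read_csv(opath, sep="\t")
        backend = get_backend(self.config.backend)
        scored = score_transcripts_semantic(obs, self.config.queries, backend)
        scored.to_csv(self._path("semantic_scores.tsv"), sep="\t", index=False)
        ret = retention_stats(obs, scored)
        ret.to_csv(self._path("retention_semantic.tsv"), sep="\t")
        self._manifest(
            "score-semantic", [opath],
            {"backend": self.config.backend, "queries": list(self.config.queries)},
            {"scored": len(scored)},
        )
        return scored

    def score_bins(self) -> pd.DataFrame:
        opath = self._require("observations.tsv", "parse")
        obs = pd.read_csv(opath, sep="\t")
        scored = score_transcripts_bins(obs, self._lexicon())
        scored.to_csv(self._path("bins.tsv"), sep="\t", index=False)
        binned = scored[scored["bin"].notna()]
        ret = retention_stats(obs, binned, phrase_bearing=binned)
        ret.to_csv(self._path("retention_bins.tsv"), sep="\t")
        self._manifest("score-bins", [opath], {},
                       {"scored": len(scored), "binned": len(binned)})
        return scored

    def _observation_values(self) -> pd.DataFrame:
        """Per-observation (taxon, replicate, row, value) for the chosen method."""
        m = self.config.method
        if m == "measured":
            p = self._require("truth_observations.tsv", "simulate")
            t = pd.read_csv(p, sep="\t")
            return t[["taxon", "replicate", "row", "value"]]
        if m == "semantic":
            p = self._require("semantic_scores.tsv", "score-semantic")
            t = pd.read_csv(p, sep="\t")
            tall = self.config.queries[0]
            return t[["taxon", "replicate", "row", tall]].rename(columns={tall: "value"})
        p = self._require("bins.tsv", "score-bins")
        t = pd.read_csv(p, sep="\t")
        t = t[t["bin"].notna()]
        return t[["taxon", "replicate", "row", "bin"]].rename(columns={"bin": "value"})

    def adjust(self) -> pd.Series:
        """Collapse per-observation values to one adjusted value per taxon."""
        table = self._observation_values()
        model = self.config.model
        if model == "blue":
            pheno = fit_blue(table)
        elif model == "blup":
            pheno = fit_blup(table)
        else:
            if self.config.method != "binned":
                raise ValueError("multinomial model requires the binned method")
            pheno = fit_multinomial(table.rename(columns={"value": "bin"}))
        label = f"{self.config.method}_{model}"
        pheno.to_tsv(self._path(f"phenotype_{label}.tsv"))
        if pheno.diagnostics is not None:
            pheno.diagnostics.to_csv(
                self._path(f"diagnostics_{label}.tsv"), sep="\t", index=False
            )
        self._manifest(
            "adjust", [], {"method": self.config.method, "model": model,
                           "variance_components": pheno.variance_components},
            {"taxa": len(pheno.values), "observations": len(table)},
        )
        return pheno.values

    def _phenotype_path(self) -> Path:
        label = f"{self.config.method}_{self.config.model}"
        return self._require(f"phenotype_{label}.tsv", "adjust")

    def gwas(self) -> pd.DataFrame:
        gpath = self._resolve("genotypes", "genotypes.tsv", "simulate")
        ppath = self._phenotype_path()
        pheno = pd.read_csv(ppath, sep="\t").set_index("taxon")["value"]
        geno = read_genotypes(gpath)
        covs = compute_pcs(geno, self.config.pcs) if self.config.pcs > 0 else None
        label = f"{self.config.method}_{self.config.model}"
        if self.config.per_chromosome:
            parts = [
                scan(geno, pheno, covs, alpha=self.config.alpha, chrom=c).table
                for c in geno.markers["chrom"].astype(str).unique()
            ]
            table = pd.concat(parts, ignore_index=True)
            m = int((~table["skipped"]).sum())
            thr = bonferroni_threshold(m, self.config.alpha)
            table["significant"] = (~table["skipped"]) & (table["neg_log10_p"] > thr)
        else:
            res = scan(geno, pheno, covs, alpha=self.config.alpha)
            table, thr = res.table, res.threshold_neg_log10
        table.to_csv(self._path(f"assoc_{label}.tsv"), sep="\t", index=False)
        curve = ld_decay(geno)
        curve.table.to_csv(self._path("ld_decay.tsv"), sep="\t", index=False)
        window = select_window(curve, self.config.window_r2)
        self._manifest(
            "gwas", [gpath, ppath],
            {"pcs": self.config.pcs, "alpha": self.config.alpha,
             "per_chromosome": self.config.per_chromosome,
             "bonferroni_neg_log10": thr, "ld_window_halfwidth": window},
            {"markers": len(table), "significant": int(table["significant"].sum())},
        )
        return table

    def annotate(self) -> pd.DataFrame:
        label = f"{self.config.method}_{self.config.model}"
        apath = self._require(f"assoc_{label}.tsv", "gwas")
        gff = self._resolve("annotation", "annotation.gff3", "simulate")
        gopath = self._resolve("go_map", "go_map.tsv", "simulate")
        namepath = self._resolve("go_names", "go_names.tsv", "simulate")
        litpath = self._resolve("literature", "literature.txt", "simulate")
        assoc_table = pd.read_csv(apath, sep="\t")
        sig = assoc_table[assoc_table["significant"]]
        ann = read_gff3_genes(gff)
        go_map = read_go_map(gopath)
        names = read_go_names(namepath)
        regions = collect_genes(sig, ann, self.config.window, analysis=label, go_map=go_map)
        lit_summary = intersect_literature(regions, read_literature_list(litpath))
        reg_df = pd.DataFrame(
            [
                {"analysis": r.analysis, "marker": r.marker, "chrom": r.chrom,
                 "pos": r.pos, "start": r.start, "end": r.end,
                 "n_genes": r.n_genes, "genes": ";".join(r.genes),
                 "literature_hit": r.literature_hit}
                for r in regions
            ]
        )
        reg_df.to_csv(self._path(f"regions_{label}.tsv"), sep="\t", index=False)
        counts = go_keyword_counts(regions, go_map, names, split_by_literature=True)
        counts.to_csv(self._path(f"go_keywords_{label}.tsv"), sep="\t", index=False)
        lit_summary.to_csv(self._path(f"literature_summary_{label}.tsv"), sep="\t", index=False)
        self._manifest(
            "annotate", [apath, gff, gopath, namepath, litpath],
            {"window": self.config.window},
            {"regions": len(regions),
             "literature_hits": int(reg_df["literature_hit"].sum()) if len(reg_df) else 0},
        )
        return reg_df

    def compare(self, label_a: str, label_b: str) -> pd.DataFrame:
        """Shared-region comparison between two completed analyses."""
        pa = self._require(f"regions_{label_a}.tsv", "annotate")
        pb = self._require(f"regions_{label_b}.tsv", "annotate")
        from .regions import CandidateRegion

        def load(p, analysis):
            df = pd.read_csv(p, sep="\t")
            return [
                CandidateRegion(
                    analysis=analysis, marker=str(r.marker), chrom=str(r.chrom),
                    pos=int(r.pos), start=int(r.start), end=int(r.end),
                    genes=tuple(str(r.genes).split(";")) if isinstance(r.genes, str) else (),
                )
                for r in df.itertuples(index=False)
            ]

        pairs = shared_regions(load(pa, label_a), load(pb, label_b))
        pairs.to_csv(self._path(f"shared_{label_a}_vs_{label_b}.tsv"), sep="\t", index=False)
        self._manifest(
            "compare", [pa, pb], {"a": label_a, "b": label_b},
            {"shared_pairs": len(pairs),
             "same_marker": int(pairs["same_marker"].sum()) if len(pairs) else 0},
        )
        return pairs

    def run_all(self) -> None:
        """simulate -> parse -> score -> adjust -> gwas -> annotate."""
        self.simulate()
        self.parse()
        if self.config.method == "semantic":
            self.score_semantic()
        elif self.config.method == "binned":
            self.score_bins()
        self.adjust()
        self.gwas()
        self.annotate()
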