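"""Synthetic field study: genotypes, heritable height, layout, transcripts.

Emulates the statistical structure of a two-replicate maize field trial
described by spoken row observations: ~650 taxa laid out over 720 rows
per replicate, biallelic SNPs with block LD, an additive height trait
with replicate/row field effects, and noisy spoken-style transcript
lines in which a height phrase appears in most (but not all)
observations.  Every downstream stage of the pipeline can therefore be
exercised end to end without any external download.

Conventions
-----------
* Genetic values are rescaled so the realized variance ratio
  Var(genetic) / (Var(genetic) + var_rep + var_row + var_resid) equals
  the requested narrow-sense heritability exactly; replicate and row
  effect draws are likewise rescaled to their target sample variance
  (the residual stays a pure Gaussian draw).  This realized-variance
  convention makes small-df components (2 replicates!) identifiable in
  parameter-recovery tests.
* The spoken bin is linked to the trait by the fixed map
  ``bin = clamp(round(3.5 + 1.5 z), 0, 7)`` on the standardized
  observation phenotype z, centering the 8-bin scale on the trait mean.
* All randomness flows from ``SimConfig.seed`` through per-operation
  child streams, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .phenoscore import PhraseLexicon
from .transcripts import FieldLayout, Observation, format_observation

__all__ = [
    "SimConfig",
    "TrueTrait",
    "simulate_genotypes",
    "layout_field",
    "field_composition",
    "simulate_trait",
    "generate_transcripts",
    "simulate_annotation",
    "simulate_go_annotations",
    "simulate_literature_list",
    "write_transcripts",
]

NATO = (
    "Alpha", "Bravo", "Charlie", "Delta", "Echo", "Foxtrot", "Golf", "Hotel",
    "India", "Juliett", "Kilo", "Lima", "Mike", "November", "Oscar", "Papa",
    "Quebec", "Romeo", "Sierra", "Tango", "Uniform", "Victor", "Whiskey",
    "Xray", "Yankee", "Zulu",
)

DEFAULT_NOISE_SENTENCES = (
    "tassels have emerged",
    "the anthers have everted",
    "brace roots at two nodes",
    "some brace roots point upward",
    "silks are yellow",
    "leaves are very much upright",
    "red to purple anthocyanins in rings",
    "some lodging in this row",
    "a few plants show leaf spotting",
    "ears are starting to fill",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic field study.

    Defaults describe the emulated trial: ~650 taxa in 2 replicates of
    720 rows, 3 observation passes per row, ~10% of transcripts lacking
    a height phrase.
    """

    n_taxa: int = 650
    n_chrom: int = 2
    markers_per_chrom: int = 1000
    chrom_length_bp: int = 50_000_000
    ld_block_len_bp: int = 750_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    n_causal: int = 5
    h2: float = 0.6
    var_rep: float = 1.0
    var_row: float = 0.5
    var_resid: float = 1.0
    n_reps: int = 2
    rows_per_rep: int = 720
    n_passes: int = 3
    participants: tuple[str, ...] = ("Delta", "Golf", "Kilo")
    omit_prob: float = 0.1
    noise_sentences: tuple[str, ...] = DEFAULT_NOISE_SENTENCES
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < min <= max <= 0.5, got {self.maf_range}")
        if not 0 <= self.h2 <= 1:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if min(self.var_rep, self.var_row, self.var_resid) < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_causal > self.n_chrom * self.markers_per_chrom:
            raise ValueError("n_causal exceeds total marker count")
        for name in ("n_taxa", "n_chrom", "markers_per_chrom", "chrom_length_bp",
                     "n_reps", "rows_per_rep", "n_passes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.omit_prob <= 1:
            raise ValueError("omit_prob must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.participants) < self.n_passes:
            raise ValueError("need at least n_passes participant names")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# stream tags for per-operation child RNGs
_S_GENO, _S_LAYOUT, _S_TRAIT, _S_TRANSCRIPT, _S_ANNOT = 1, 2, 3, 4, 5


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _simulate_block(
    rng: np.random.Generator, n_hap: int, p: float, rhos: np.ndarray
) -> np.ndarray:
    """Haplotype block as a Markov chain over {0,1}.

    Marker j+1 copies marker j with probability ``rhos[j]`` and is
    otherwise redrawn Bernoulli(p); stationary frequency is p at every
    marker and corr(marker_j, marker_{j+k}) = prod(rhos[j:j+k]).
    """
    m = len(rhos) + 1
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < p
    for j in range(1, m):
        keep = rng.random(n_hap) < rhos[j - 1]
        fresh = rng.random(n_hap) < p
        H[:, j] = np.where(keep, H[:, j - 1], fresh)
    return H


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Biallelic SNP dosages with block LD decaying over distance.

    Markers are evenly spaced along each chromosome.  The chromosome is
    partitioned into blocks of ``ld_block_len_bp``; within a block all
    markers share an allele frequency drawn from ``maf_range`` and are
    generated from a haplotype Markov chain whose adjacent-marker
    correlation is exp(-2 d / L) for spacing d and block length L, so
    r² ~ exp(-4 d / L) declines with distance; markers in different
    blocks are independent.  ``ld_block_len_bp = 0`` turns LD off.
    """
    rng = config.rng(_S_GENO)
    taxa = [f"TX{i:04d}" for i in range(config.n_taxa)]
    n_hap = 2 * config.n_taxa
    lo, hi = config.maf_range
    spacing = config.chrom_length_bp / config.markers_per_chrom
    if spacing < 1:
        raise ValueError("more markers than base pairs on a chromosome")
    all_markers, dosage_cols = [], []
    for c in range(1, config.n_chrom + 1):
        pos = (np.arange(config.markers_per_chrom) * spacing + spacing / 2).astype(np.int64) + 1
        L = config.ld_block_len_bp
        block_id = pos // L if L > 0 else np.arange(len(pos))
        for b in np.unique(block_id):
            idx = np.where(block_id == b)[0]
            p = rng.uniform(lo, hi)
            if L > 0 and len(idx) > 1:
                d = np.diff(pos[idx]).astype(float)
                rhos = np.exp(-2.0 * d / L)
            else:
                rhos = np.zeros(max(len(idx) - 1, 0))
            H = _simulate_block(rng, n_hap, p, rhos)
            dos = (H[0::2] + H[1::2]).astype(float)
            dosage_cols.append(dos)
            for k in idx:
                all_markers.append((f"S{c}_{pos[k]}", str(c), int(pos[k]), "A", "T"))
    dosages = np.concatenate(dosage_cols, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    markers = pd.DataFrame(all_markers, columns=["marker", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(taxa, markers, dosages)


# ---------------------------------------------------------------------------
# Field layout
# ---------------------------------------------------------------------------


def field_composition(
    panel_taxa: Sequence[str],
    n_seed_increase: int = 31,
    n_experimental_control: int = 8,
    n_positive_control: int = 25,
    n_duplicated: int = 1,
) -> tuple[list[str], list[str]]:
    """Row composition of one replicate of the emulated trial.

    31 seed-increase rows, 8 experimental-control rows (one control
    line), 25 positive-control rows, one row per panel taxon, and one
    duplicated panel row: with a 655-taxon panel this is 720 rows.
    Returns (taxon per row, block label per row).
    """
    panel = list(panel_taxa)
    taxa = (
        [f"SEED{i:03d}" for i in range(n_seed_increase)]
        + ["CTRL_B73"] * n_experimental_control
        + [f"POS{i:03d}" for i in range(n_positive_control)]
        + panel
        + panel[:n_duplicated]
    )
    blocks = (
        ["block1"] * n_seed_increase
        + ["block2"] * (n_experimental_control + n_positive_control + len(panel) + n_duplicated)
    )
    return taxa, blocks


def layout_field(
    taxa: Sequence[str],
    config: SimConfig,
    blocks: Sequence[str] | None = None,
) -> FieldLayout:
    """Randomized field layout: each replicate permutes the requested rows.

    ``taxa`` gives one taxon per row of a replicate (duplicates allowed,
    e.g. repeated control rows) and must match ``rows_per_rep``.  Rows
    are numbered uniquely across the whole field, replicate 1 first.
    """
    if len(taxa) != config.rows_per_rep:
        raise ValueError(
            f"composition has {len(taxa)} rows but rows_per_rep = {config.rows_per_rep}"
        )
    if blocks is None:
        blocks = ["block1"] * len(taxa)
    rng = config.rng(_S_LAYOUT)
    records = []
    row_no = 1
    for rep in range(1, config.n_reps + 1):
        order = rng.permutation(len(taxa))
        for i in order:
            records.append((row_no, taxa[i], rep, blocks[i]))
            row_no += 1
    return FieldLayout(pd.DataFrame(records, columns=["row", "taxon", "replicate", "block"]))


# ---------------------------------------------------------------------------
# Trait
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueTrait:
    """Ground truth behind the synthetic phenotypes.

    ``genetic``: per-taxon genetic value; ``observations``: one realized
    phenotype per (row, replicate, pass); ``causal``: causal markers and
    effects; the ``var_*`` fields record the realized noise components.
    """

    genetic: pd.Series
    observations: pd.DataFrame  # row, replicate, taxon, pass_no, value
    causal: pd.DataFrame  # marker, chrom, pos, effect
    h2: float
    var_rep: float
    var_row: float
    var_resid: float

    def taxon_means(self) -> pd.Series:
        return self.observations.groupby("taxon")["value"].mean()

    def realized_h2(self) -> float:
        """Var(genetic contribution) / Var(phenotype) over observations."""
        g = self.genetic.reindex(self.observations["taxon"]).to_numpy()
        return float(np.var(g) / np.var(self.observations["value"].to_numpy()))


def _rescaled(draws: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale centered draws so their mean square is exactly target_var.

    The ddof=1 convention matters: REML estimates a variance component
    from its q realized effects with q-1 degrees of freedom (one lost
    to the mean), so rescaling to the ddof=1 sample variance is what
    makes recovery centered on the target even at q = 2 replicates.
    """
    if target_var == 0 or len(draws) < 2:
        return np.zeros_like(draws)
    draws = draws - draws.mean()
    sv = draws.var(ddof=1)
    return draws * np.sqrt(target_var / sv) if sv > 0 else draws


def simulate_trait(
    genotypes: GenotypeMatrix, layout: FieldLayout, config: SimConfig
) -> TrueTrait:
    """Additive height trait with replicate, row and residual effects.

    Causal markers are sampled among markers with realized MAF >= 0.2
    (falling back to the most polymorphic markers if too few qualify)
    with equal-magnitude, alternating-sign effects, and genetic values
    are rescaled so the realized heritability equals ``h2``.  Each field
    row is observed ``n_passes`` times; passes share the row's genetic,
    replicate and row effects and differ by the residual.
    """
    rng = config.rng(_S_TRAIT)
    layout_taxa = set(layout.table["taxon"])
    geno_taxa = set(genotypes.taxa)
    known = sorted(layout_taxa & geno_taxa)
    if not known:
        raise ValueError("layout taxa do not overlap genotype taxa")

    noise_total = config.var_rep + config.var_row + config.var_resid
    if config.h2 > 0 and config.n_causal == 0:
        raise ValueError("h2 > 0 requires n_causal >= 1")
    if config.h2 == 1 and noise_total > 0:
        raise ValueError("h2 = 1 requires all noise variance components to be 0")

    if config.n_causal > 0:
        maf = genotypes.maf()
        eligible = np.where(maf >= 0.2)[0]
        if len(eligible) < config.n_causal:
            eligible = np.argsort(maf)[::-1][: max(config.n_causal, 1)]
        causal_idx = np.sort(rng.choice(eligible, size=config.n_causal, replace=False))
        effects = np.where(np.arange(config.n_causal) % 2 == 0, 1.0, -1.0)
        tx_index = {t: i for i, t in enumerate(genotypes.taxa)}
        dos = genotypes.dosages[:, causal_idx]
        dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
        g_all = dos @ effects
        g = np.array([g_all[tx_index[t]] for t in known])
    else:
        causal_idx = np.array([], dtype=int)
        effects = np.array([])
        g = np.zeros(len(known))

    g = g - g.mean()
    vg = g.var(ddof=1) if len(g) > 1 else 0.0
    if config.h2 == 0:
        g[:] = 0.0
        scale = 0.0
    elif config.h2 == 1:
        scale = 1.0
    else:
        if vg == 0:
            raise ValueError("causal markers are monomorphic; genetic variance is 0")
        target_vg = config.h2 / (1 - config.h2) * noise_total
        if noise_total == 0:
            raise ValueError("0 < h2 < 1 requires some noise variance")
        scale = np.sqrt(target_vg / vg)
    g = g * scale
    effects = effects * scale
    genetic = pd.Series(g, index=known, name="genetic")

    lt = layout.table[layout.table["taxon"].isin(known)].reset_index(drop=True)
    reps = sorted(lt["replicate"].unique())
    rep_eff = dict(zip(reps, _rescaled(rng.normal(size=len(reps)), config.var_rep)))
    rows = lt["row"].to_numpy()
    row_eff = dict(zip(rows, _rescaled(rng.normal(size=len(rows)), config.var_row)))

    recs = []
    for rec in lt.itertuples(index=False):
        core = genetic[rec.taxon] + rep_eff[rec.replicate] + row_eff[rec.row]
        resid = (
            rng.normal(0.0, np.sqrt(config.var_resid), size=config.n_passes)
            if config.var_resid > 0
            else np.zeros(config.n_passes)
        )
        for p in range(config.n_passes):
            recs.append((rec.row, rec.replicate, rec.taxon, p + 1, core + resid[p]))
    obs = pd.DataFrame(recs, columns=["row", "replicate", "taxon", "pass_no", "value"])

    causal = genotypes.markers.iloc[causal_idx][["marker", "chrom", "pos"]].copy()
    causal["effect"] = effects
    return TrueTrait(
        genetic=genetic,
        observations=obs,
        causal=causal.reset_index(drop=True),
        h2=config.h2,
        var_rep=config.var_rep,
        var_row=config.var_row,
        var_resid=config.var_resid,
    )


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------


def true_bin(z: np.ndarray) -> np.ndarray:
    """Spoken-bin link function: clamp(round(3.5 + 1.5 z), 0, 7)."""
    return np.clip(np.floor(3.5 + 1.5 * np.asarray(z) + 0.5), 0, 7).astype(int)


def generate_transcripts(
    layout: FieldLayout,
    trait: TrueTrait,
    lexicon: PhraseLexicon,
    config: SimConfig,
    with_truth: bool = False,
):
    """Spoken-style observation lines for every (row, replicate, pass).

    The standardized pass phenotype is mapped to a bin by
    :func:`true_bin`; a phrase is drawn uniformly from that bin's
    phrases unless the observation omits height (probability
    ``omit_prob``), and one or two height-unrelated noise sentences are
    appended.  Participant names cycle over the passes.

    Returns a list of :class:`~spokenpheno.transcripts.Observation`
    (and, with ``with_truth``, a truth DataFrame for test oracles).
    """
    missing_bins = set(range(8)) - lexicon.bins_covered
    if missing_bins:
        raise ValueError(f"lexicon lacks phrases for bins {sorted(missing_bins)}")
    rng = config.rng(_S_TRANSCRIPT)
    obs = trait.observations
    vals = obs["value"].to_numpy()
    z = (vals - vals.mean()) / vals.std()
    bins = true_bin(z)
    phrases_by_bin = {b: lexicon.phrases_for_bin(b) for b in range(8)}
    noise = list(config.noise_sentences)
    observations, truth = [], []
    for i, rec in enumerate(obs.itertuples(index=False)):
        participant = config.participants[(rec.pass_no - 1) % len(config.participants)]
        omitted = bool(rng.random() < config.omit_prob)
        sentences = []
        if not omitted:
            opts = phrases_by_bin[bins[i]]
            phrase = opts[rng.integers(len(opts))]
            sentences.append(f"Plants are {phrase}" if " " not in phrase else phrase)
        if noise:
            k = int(rng.integers(1, min(2, len(noise)) + 1))
            picks = rng.choice(len(noise), size=k, replace=False)
            sentences.extend(noise[j] for j in picks)
        if not sentences:
            sentences = ["row observed"]
        text = ". ".join(s[0].upper() + s[1:] for s in sentences) + "."
        observations.append(Observation(participant=participant, row=int(rec.row), text=text))
        if with_truth:
            truth.append((rec.row, rec.replicate, rec.taxon, rec.pass_no,
                          participant, rec.value, int(bins[i]), omitted))
    if with_truth:
        tdf = pd.DataFrame(
            truth,
            columns=["row", "replicate", "taxon", "pass_no", "participant",
                     "value", "bin", "omitted"],
        )
        return observations, tdf
    return observations


def write_transcripts(observations: Sequence[Observation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for o in observations:
            fh.write(format_observation(o) + "\n")


# ---------------------------------------------------------------------------
# Annotation, GO and literature-list stand-ins (synthetic)
# ---------------------------------------------------------------------------

# small synthetic GO vocabulary; hormone terms first
GO_TERMS = {
    "GO:0009734": "auxin-activated signaling pathway",
    "GO:0009851": "auxin biosynthetic process",
    "GO:0009684": "indoleacetic acid biosynthetic process",
    "GO:0016132": "brassinosteroid biosynthetic process",
    "GO:0009742": "brassinosteroid mediated signaling pathway",
    "GO:0009686": "gibberellin biosynthetic process",
    "GO:0009740": "gibberellic acid mediated signaling pathway",
    "GO:0009737": "response to abscisic acid",
    "GO:0015979": "photosynthesis",
    "GO:0006281": "DNA repair",
    "GO:0006355": "regulation of transcription, DNA-templated",
    "GO:0048366": "leaf development",
    "GO:0009908": "flower development",
    "GO:0005975": "carbohydrate metabolic process",
    "GO:0006979": "response to oxidative stress",
    "GO:0048589": "developmental growth",
}


def simulate_annotation(
    config: SimConfig, gene_spacing_bp: int = 40_000, gene_length_bp: int = 4_000
) -> pd.DataFrame:
    """Synthetic gene models tiling the simulated chromosomes.

    Returns a DataFrame (gene_id, chrom, start, end) in 1-based
    inclusive coordinates, deterministic for a given config.
    """
    recs = []
    for c in range(1, config.n_chrom + 1):
        n_genes = config.chrom_length_bp // gene_spacing_bp
        for i in range(n_genes):
            start = i * gene_spacing_bp + 1_000
            recs.append((f"GM{c:02d}G{i:05d}", str(c), start + 1, start + gene_length_bp))
    return pd.DataFrame(recs, columns=["gene_id", "chrom", "start", "end"])


def simulate_go_annotations(
    annotation: pd.DataFrame, config: SimConfig, mean_terms: float = 2.0
) -> pd.DataFrame:
    """Random gene -> GO assignments from the synthetic GO vocabulary."""
    rng = config.rng(_S_ANNOT)
    go_ids = list(GO_TERMS)
    recs = []
    for gene in annotation["gene_id"]:
        k = min(rng.poisson(mean_terms), len(go_ids))
        for j in rng.choice(len(go_ids), size=k, replace=False):
            recs.append((gene, go_ids[j]))
    return pd.DataFrame(recs, columns=["gene_id", "go_id"])


def simulate_literature_list(
    annotation: pd.DataFrame,
    causal: pd.DataFrame,
    config: SimConfig,
    near_bp: int = 50_000,
    n_decoys: int = 20,
) -> list[str]:
    """Synthetic literature height-gene list: genes near causal loci plus decoys."""
    rng = config.rng(_S_ANNOT + 100)
    hits = []
    for rec in causal.itertuples(index=False):
        sel = annotation[
            (annotation["chrom"] == str(rec.chrom))
            & (annotation["end"] >= rec.pos - near_bp)
            & (annotation["start"] <= rec.pos + near_bp)
        ]
        hits.extend(sel["gene_id"].tolist())
    pool = annotation.loc[~annotation["gene_id"].isin(hits), "gene_id"]
    decoys = pool.iloc[rng.choice(len(pool), size=min(n_decoys, len(pool)), replace=False)]
    return sorted(set(hits) | set(decoys))


def write_gff3(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as a minimal GFF3 (feature type 'gene')."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotation.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\tsynthetic\tgene\t{rec.start}\t{rec.end}\t.\t+\t.\t"
                f"ID=gene:{rec.gene_id};Name={rec.gene_id}\n"
            )
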