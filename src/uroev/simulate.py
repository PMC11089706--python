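"""Synthetic cohorts, genomes, counts, reads and qPCR tables.

The generator emulates the statistical structure the analysis stages
assume, on a miniature genome, so every downstream stage is testable
without access to patient data:

* a case/control cohort with male-skewed composition, ages 40-80 and
  per-group obesity/hypertension prevalences;
* a genome whose host genes carry intronic snoRNA genes, each snoRNA
  aligned to exactly one quantification region (the planted markers);
* NB-distributed region counts (variance mu + alpha mu^2) with planted
  negative case-vs-control log2 fold changes on the markers, a planted
  male/female effect on a larger set of regions that dominates global
  variance, heavy-tailed (log2-normal) baseline intensities typical of
  small-RNA profiles, and a constant high-expression reference-gene run;
* per-read placements that are peaked (RNA-like) for clean samples and
  genome-uniform (DNA-like) for the designated contaminated samples;
* duplicate-reaction qPCR CT values tied to the same latent marker
  expression as the counts, plus a stable reference-gene assay.

Every generator is a pure function of its config (seed included): equal
configs give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (GeneAnnotation, GenomeIndex, ReadSet, SampleSheet,
                 region_key, write_annotation_gtf, write_bed_reads,
                 write_matrix, write_sample_sheet)
from .regions import RegionCountMatrix, RegionGrid, tile_genome

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_genome",
    "simulate_counts",
    "simulate_reads",
    "simulate_qpcr",
    "simulate_all",
    "write_fixture_set",
]

# stage tags keep per-stage RNG streams independent but seed-derived
_STAGE = {"cohort": 1, "genome": 2, "counts": 3, "reads": 4, "qpcr": 5}

REFERENCE_GENE = "REFG1"
REFERENCE_ASSAY = "REFG1"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study shape."""

    seed: int = 0
    # cohort (validation-cohort shape: 54 cases / 24 controls, of which
    # 7 + 8 are DNA-contaminated, leaving a 47/16 discovery cohort)
    n_case: int = 54
    n_control: int = 24
    gender_prob_case: float = 0.77
    gender_prob_control: float = 0.94
    age_range: tuple[float, float] = (40.0, 80.0)
    obesity_prev: tuple[float, float] = (0.30, 0.17)        # (case, control)
    hypertension_prev: tuple[float, float] = (0.61, 0.58)   # (case, control)
    n_contaminated: tuple[int, int] | int = (7, 8)          # (case, control)
    # genome
    n_contigs: int = 2
    contig_length: int = 100_000
    region_width: int = 100
    n_reference_regions: int = 3
    # expression model
    n_marker_regions: int = 13
    marker_log2fc: tuple[float, ...] = (
        -3.45, -1.63, -2.19, -2.19, -1.73, -2.94, -2.27,
        -2.36, -2.31, -1.80, -3.49, -1.80, -2.18)
    marker_baseline: tuple[float, float] = (6.0, 0.5)   # log2 mean, sd
    marker_bio_sd: float = 1.5
    n_gender_regions: int = 100
    gender_log2fc: float = 2.0
    baseline_log_mean: tuple[float, float] = (2.0, 2.5)  # log2 mu, sigma
    baseline_log2_max: float = 9.0   # no background locus above this level
    reference_log2_level: float = 10.0
    nb_dispersion: float = 0.4
    library_size_sigma: float = 0.3
    # reads
    read_length: int = 50
    # qPCR CT model: CT = intercept - slope * log2(latent) + noise
    qpcr_slope: float = 1.0
    qpcr_intercept: float = 30.0
    qpcr_noise_sd: float = 0.25

    def __post_init__(self):
        for p in (self.gender_prob_case, self.gender_prob_control,
                  *self.obesity_prev, *self.hypertension_prev):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if len(self.marker_log2fc) != self.n_marker_regions:
            raise ValueError("n_marker_regions must equal len(marker_log2fc)")
        if min(self.n_case, self.n_control, self.n_contigs,
               self.n_marker_regions, self.n_gender_regions) < 0:
            raise ValueError("counts must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        nc = self.n_contaminated
        total = sum(nc) if isinstance(nc, (tuple, list)) else nc
        if total > self.n_case + self.n_control:
            raise ValueError("n_contaminated exceeds cohort size")

    @property
    def contaminated_per_group(self) -> tuple[int, int]:
        nc = self.n_contaminated
        if isinstance(nc, (tuple, list)):
            return int(nc[0]), int(nc[1])
        # split a single total proportionally to group sizes
        n_case = round(nc * self.n_case / (self.n_case + self.n_control))
        return int(n_case), int(nc - n_case)

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STAGE[stage]]))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config key(s): "
                             f"{sorted(unknown)}")
        for key in ("age_range", "obesity_prev", "hypertension_prev",
                    "marker_log2fc", "marker_baseline", "baseline_log_mean",
                    "n_contaminated"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generator (oracle for recovery tests)."""

    marker_region_ids: list[str]
    marker_gene_names: list[str]
    marker_log2fc: list[float]
    gender_region_ids: list[str]
    reference_region_ids: list[str]
    contaminated_sample_ids: list[str]
    marker_latent: pd.DataFrame      # markers (gene names) x samples
    gender_log2fc: float
    library_sizes: pd.Series

    def to_json(self) -> str:
        d = {
            "marker_region_ids": self.marker_region_ids,
            "marker_gene_names": self.marker_gene_names,
            "marker_log2fc": self.marker_log2fc,
            "gender_region_ids": self.gender_region_ids,
            "reference_region_ids": self.reference_region_ids,
            "contaminated_sample_ids": self.contaminated_sample_ids,
            "gender_log2fc": self.gender_log2fc,
            "marker_latent": self.marker_latent.to_dict(),
            "library_sizes": self.library_sizes.to_dict(),
        }
        return json.dumps(d, indent=1)


def simulate_cohort(config: SimulationConfig) -> SampleSheet:
    """Cohort sheet: group, gender, age, risk factors, DNA/RNA ratio.

    Gender is Bernoulli per group, age uniform on ``age_range``, obesity
    and hypertension Bernoulli with per-group prevalence. The designated
    contaminated samples get ``dna_rna_ratio > 0``; clean samples 0.
    """
    rng = config.rng("cohort")
    n_cont_case, n_cont_ctrl = config.contaminated_per_group
    if n_cont_case > config.n_case or n_cont_ctrl > config.n_control:
        raise ValueError("contaminated samples exceed group size")
    rows = []
    for group, n, p_male, (p_ob, p_ht), n_cont in (
            ("case", config.n_case, config.gender_prob_case,
             (config.obesity_prev[0], config.hypertension_prev[0]),
             n_cont_case),
            ("control", config.n_control, config.gender_prob_control,
             (config.obesity_prev[1], config.hypertension_prev[1]),
             n_cont_ctrl)):
        contaminated = rng.choice(n, size=n_cont, replace=False) if n else []
        contaminated = set(np.asarray(contaminated).tolist())
        for i in range(n):
            rows.append({
                "sample_id": f"{group}{i + 1:02d}",
                "group": group,
                "gender": "male" if rng.random() < p_male else "female",
                "age": float(np.round(rng.uniform(*config.age_range), 1)),
                "dna_rna_ratio": (float(np.round(rng.uniform(0.1, 1.0), 3))
                                  if i in contaminated else 0.0),
                "obesity": bool(rng.random() < p_ob),
                "hypertension": bool(rng.random() < p_ht),
            })
    return SampleSheet(rows=pd.DataFrame(rows))


def _genome_layout(config: SimulationConfig):
    """Deterministic gene/snoRNA/reference placement on the contigs."""
    w = config.region_width
    L = config.contig_length
    if L < 10 * config.read_length:
        raise ValueError("contig_length must be >= 10 * read_length")
    n_sno_per_contig = [config.n_marker_regions // config.n_contigs +
                        (1 if c < config.n_marker_regions % config.n_contigs
                         else 0)
                        for c in range(config.n_contigs)]
    unit = 5 * w   # exon .. gap .. snoRNA region .. gap .. next exon
    layout = []
    sno_counter = 0
    for c in range(config.n_contigs):
        contig = f"chrS{c + 1}"
        n_sno = n_sno_per_contig[c]
        g0 = (L // 10 // w) * w
        gene_len = n_sno * unit + w
        if g0 + gene_len > L:
            raise ValueError("host gene does not fit on contig; increase "
                             "contig_length or reduce markers")
        exons = [(g0 + k * unit, g0 + k * unit + w) for k in range(n_sno + 1)]
        snos = []
        for k in range(n_sno):
            s = g0 + k * unit + 2 * w
            sno_counter += 1
            snos.append((f"SNOsim{sno_counter:02d}", s, s + w))
        layout.append({"contig": contig, "host": (g0, g0 + gene_len),
                       "exons": exons, "snos": snos})
    # reference gene: a run of consecutive regions on the first contig,
    # placed after the host gene, region-aligned
    if config.n_reference_regions == 0:
        return layout, None
    ref_start = ((L * 9 // 10) // w) * w
    ref_len = config.n_reference_regions * w
    if ref_start + ref_len > L:
        raise ValueError("reference gene does not fit on contig")
    return layout, (layout[0]["contig"], ref_start, ref_start + ref_len)


def simulate_genome(config: SimulationConfig
                    ) -> tuple[GenomeIndex, GeneAnnotation]:
    """Miniature genome: host genes with intronic snoRNAs plus a reference.

    Each contig carries one lincRNA host gene whose introns contain
    snoRNA genes, each occupying exactly one quantification region
    (strictly inside an intron); the first contig additionally carries a
    protein-coding reference gene spanning ``n_reference_regions``
    consecutive regions. Placement is deterministic given the config.
    """
    layout, ref_span = _genome_layout(config)
    index = GenomeIndex(tuple((l["contig"], config.contig_length)
                              for l in layout))
    recs = []
    for li, l in enumerate(layout):
        host = f"HOSTG{li + 1}"
        g0, g1 = l["host"]
        recs.append((host, host, "lincRNA", l["contig"], g0, g1, "+", "gene"))
        for (es, ee) in l["exons"]:
            recs.append((host, host, "lincRNA", l["contig"], es, ee, "+",
                         "exon"))
        for (name, ss, se) in l["snos"]:
            recs.append((name, name, "snoRNA", l["contig"], ss, se, "+",
                         "gene"))
            recs.append((name, name, "snoRNA", l["contig"], ss, se, "+",
                         "exon"))
    if ref_span is not None:
        ref_contig, ref_s, ref_e = ref_span
        recs.append((REFERENCE_GENE, REFERENCE_GENE, "protein_coding",
                     ref_contig, ref_s, ref_e, "+", "gene"))
        recs.append((REFERENCE_GENE, REFERENCE_GENE, "protein_coding",
                     ref_contig, ref_s, ref_e, "+", "exon"))
    ann = GeneAnnotation(records=pd.DataFrame(
        recs, columns=["gene_id", "gene_name", "biotype", "contig", "start",
                       "end", "strand", "feature"]))
    return index, ann


def _marker_regions(config: SimulationConfig, annotation: GeneAnnotation
                    ) -> tuple[list[str], list[str]]:
    """(region keys, gene names) of the planted snoRNA marker regions."""
    snos = annotation.by_biotype("snoRNA").sort_values("gene_name")
    keys = [region_key(r.contig, r.start, r.end)
            for r in snos.itertuples(index=False)]
    return keys, snos["gene_name"].tolist()


def _reference_regions(config: SimulationConfig, annotation: GeneAnnotation
                       ) -> list[str]:
    ref = annotation.genes()
    ref = ref[ref["gene_name"] == REFERENCE_GENE]
    if ref.empty:
        return []
    ref = ref.iloc[0]
    w = config.region_width
    return [region_key(ref["contig"], s, s + w)
            for s in range(int(ref["start"]), int(ref["end"]), w)]


def simulate_counts(config: SimulationConfig, grid: RegionGrid,
                    sheet: SampleSheet, annotation: GeneAnnotation,
                    ) -> tuple[RegionCountMatrix, SimulationTruth]:
    """NB region counts with planted marker, gender and reference structure.

    log2 q_ij = b0_i + marker_lfc_i * case_j + gender_lfc_i * male_j
    (+ a per-sample biological deviation on marker regions, shared with
    the qPCR latent); K_ij ~ NB(mean s_j q_ij, variance mu + alpha mu^2)
    with log-normal library size s_j. Reference-gene regions are held at a
    constant latent level with Poisson (alpha = 0) noise — a deliberately
    stable transcript for the reference screen to find.
    """
    if config.nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    rng = config.rng("counts")
    regions = grid.to_frame()
    R = len(regions)
    samples = sheet.sample_ids
    n = len(samples)
    case = (sheet.rows["group"] == "case").to_numpy(dtype=float)
    male = (sheet.rows["gender"] == "male").to_numpy(dtype=float)

    marker_keys, marker_names = _marker_regions(config, annotation)
    ref_keys = _reference_regions(config, annotation)
    key_pos = {k: i for i, k in enumerate(regions.index)}
    m_idx = np.array([key_pos[k] for k in marker_keys], dtype=int)
    r_idx = np.array([key_pos[k] for k in ref_keys], dtype=int)

    mu0, sig0 = config.baseline_log_mean
    # heavy-tailed background, truncated so no background locus dominates
    # the library over the planted reference transcript
    b0 = np.minimum(rng.normal(mu0, sig0, R), config.baseline_log2_max)
    b0[m_idx] = rng.normal(*config.marker_baseline, size=len(m_idx))
    b0[r_idx] = config.reference_log2_level

    # gender-effect regions: background only (not markers / reference)
    forbidden = set(m_idx.tolist()) | set(r_idx.tolist())
    candidates = np.array([i for i in range(R) if i not in forbidden])
    n_gender = min(config.n_gender_regions, len(candidates))
    g_idx = rng.choice(candidates, size=n_gender, replace=False) \
        if n_gender else np.array([], dtype=int)

    lfc = np.zeros(R)
    lfc[m_idx] = np.asarray(config.marker_log2fc, dtype=float)
    glfc = np.zeros(R)
    glfc[g_idx] = config.gender_log2fc

    log2q = (b0[:, None] + lfc[:, None] * case[None, :]
             + glfc[:, None] * male[None, :])
    if len(m_idx) and config.marker_bio_sd > 0:
        log2q[m_idx] += rng.normal(0.0, config.marker_bio_sd,
                                   size=(len(m_idx), n))
    q = np.power(2.0, log2q)

    s = np.exp(rng.normal(0.0, config.library_size_sigma, n))
    mu = q * s[None, :]

    alpha = np.full(R, config.nb_dispersion)
    alpha[r_idx] = 0.0
    counts = np.empty((R, n), dtype=np.int64)
    poisson_rows = alpha < 1e-12
    if poisson_rows.any():
        counts[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        r_par = 1.0 / alpha[nb_rows]
        p_par = r_par[:, None] / (r_par[:, None] + mu[nb_rows])
        counts[nb_rows] = rng.negative_binomial(r_par[:, None], p_par)

    counts_df = pd.DataFrame(counts, index=regions.index, columns=samples)
    rcm = RegionCountMatrix(regions=regions, counts=counts_df,
                            counting_mode="start")
    contaminated = sheet.rows.loc[sheet.rows["dna_rna_ratio"] > 0,
                                  "sample_id"].tolist()
    latent = pd.DataFrame(q[m_idx], index=marker_names, columns=samples) \
        if len(m_idx) else pd.DataFrame(columns=samples)
    truth = SimulationTruth(
        marker_region_ids=list(marker_keys),
        marker_gene_names=list(marker_names),
        marker_log2fc=list(map(float, config.marker_log2fc)),
        gender_region_ids=[regions.index[i] for i in g_idx],
        reference_region_ids=list(ref_keys),
        contaminated_sample_ids=contaminated,
        marker_latent=latent,
        gender_log2fc=float(config.gender_log2fc),
        library_sizes=pd.Series(s, index=samples),
    )
    return rcm, truth


def simulate_reads(config: SimulationConfig, grid: RegionGrid,
                   counts: RegionCountMatrix, truth: SimulationTruth,
                   ) -> dict[str, ReadSet]:
    """Per-sample read placements as BED-style intervals.

    RNA-like (clean) samples: each region receives exactly its count of
    fixed-length reads, starting uniformly within the region (reads may
    run across region boundaries; they are truncated at the contig end).
    DNA-like (contaminated) samples: the same total read number is placed
    uniformly over the whole genome, emulating genomic-DNA coverage.
    """
    if config.read_length > min(l for _, l in grid.index.contigs):
        raise ValueError("read_length exceeds contig length")
    rng = config.rng("reads")
    regions = counts.regions
    contigs = regions["contig"].to_numpy()
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    lengths = grid.index.lengths
    contaminated = set(truth.contaminated_sample_ids)
    contig_names = [c for c, _ in grid.index.contigs]
    contig_lens = np.array([lengths[c] for c in contig_names], dtype=float)
    contig_prob = contig_lens / contig_lens.sum()
    out = {}
    for sample in counts.sample_ids:
        c = counts.counts[sample].to_numpy()
        total = int(c.sum())
        if sample in contaminated:
            pick = rng.choice(len(contig_names), size=total, p=contig_prob)
            read_contig = np.array(contig_names, dtype=object)[pick]
            high = contig_lens[pick] - config.read_length
            read_start = (rng.random(total) * np.maximum(high, 1)).astype(
                np.int64)
        else:
            read_contig = np.repeat(contigs, c)
            lo = np.repeat(starts, c)
            width = np.repeat(ends - starts, c)
            read_start = lo + rng.integers(0, width)
        read_end = read_start + config.read_length
        clip = np.array([lengths[ct] for ct in read_contig], dtype=np.int64) \
            if len(read_contig) else np.array([], dtype=np.int64)
        read_end = np.minimum(read_end, clip) if len(read_contig) else read_end
        df = pd.DataFrame({"contig": read_contig,
                           "start": read_start.astype(np.int64),
                           "end": read_end.astype(np.int64),
                           "strand": "."})
        df = df.sort_values(["contig", "start"], kind="stable") \
            .reset_index(drop=True)
        out[sample] = ReadSet(sample_id=sample, intervals=df)
    return out


def simulate_qpcr(config: SimulationConfig, sheet: SampleSheet,
                  truth: SimulationTruth,
                  ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Duplicate-reaction CT table tied to the latent marker expression.

    CT = intercept - slope * log2(latent) + Normal(0, noise_sd) per
    reaction, clipped to [1, 45]; the reference assay comes from a
    constant latent level. Returns (ct_table, reference_map).
    """
    if config.qpcr_slope <= 0:
        raise ValueError("qpcr_slope must be > 0")
    rng = config.rng("qpcr")
    rows = []
    assays = list(truth.marker_latent.index) + [REFERENCE_ASSAY]
    ref_latent = float(2.0 ** config.reference_log2_level)
    for assay in assays:
        for sample in sheet.sample_ids:
            latent = ref_latent if assay == REFERENCE_ASSAY \
                else float(truth.marker_latent.loc[assay, sample])
            base_ct = config.qpcr_intercept \
                - config.qpcr_slope * np.log2(latent)
            for rep in (1, 2):
                noise = rng.normal(0.0, config.qpcr_noise_sd) \
                    if config.qpcr_noise_sd > 0 else 0.0
                rows.append({"sample_id": sample, "assay_id": assay,
                             "replicate": rep,
                             "ct": float(np.clip(base_ct + noise, 1.0, 45.0))})
    refmap = {a: REFERENCE_ASSAY for a in truth.marker_latent.index}
    return pd.DataFrame(rows), refmap


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator stage; returns a dict of all artifacts."""
    sheet = simulate_cohort(config)
    index, annotation = simulate_genome(config)
    grid = tile_genome(index, width=config.region_width)
    counts, truth = simulate_counts(config, grid, sheet, annotation)
    reads = simulate_reads(config, grid, counts, truth)
    ct_table, refmap = simulate_qpcr(config, sheet, truth)
    return {"config": config, "sheet": sheet, "index": index,
            "annotation": annotation, "grid": grid, "counts": counts,
            "truth": truth, "reads": reads, "ct_table": ct_table,
            "refmap": refmap}


def write_fixture_set(config: SimulationConfig, outdir) -> dict:
    """Write the full fixture set to a directory (all plain text)."""
    art = simulate_all(config)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "genome.fai"), "wt") as fh:
        for name, length in art["index"].contigs:
            fh.write(f"{name}\t{length}\n")
    write_annotation_gtf(art["annotation"], os.path.join(outdir,
                                                         "annotation.gtf"))
    reads_dir = os.path.join(outdir, "reads")
    os.makedirs(reads_dir, exist_ok=True)
    for sample, rs in art["reads"].items():
        write_bed_reads(rs, os.path.join(reads_dir, f"{sample}.bed"))
    write_matrix(art["counts"].counts, os.path.join(outdir, "counts.tsv"))
    write_sample_sheet(art["sheet"], os.path.join(outdir, "samples.tsv"))
    art["ct_table"].to_csv(os.path.join(outdir, "qpcr.tsv"), sep="\t",
                           index=False)
    pd.Series(art["refmap"], name="reference_assay").rename_axis(
        "assay_id").to_csv(os.path.join(outdir, "refmap.tsv"), sep="\t")
    with open(os.path.join(outdir, "truth.json"), "wt") as fh:
        fh.write(art["truth"].to_json())
    return art
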