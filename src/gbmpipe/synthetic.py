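"""Synthetic multi-platform cohort with planted, recoverable ground truth.

Emulates the platform roster of a tumor/control brain-cancer cohort: exon
and gene expression matrices (tumor + control columns), a transcript
annotation consistent with the exon matrix, clinical survival records drawn
from an exponential proportional-hazards model, aCGH probe log-ratios with
planted gain/loss segments plus blood-control arrays, genotype matrices in
Hardy-Weinberg proportions, promoter methylation signals, a miRNA matrix
with a synthetic target annotation, and 384-well screening plates with a
smooth spatial background and spiked hits.

Every random draw flows from a single seed; identical configurations produce
byte-identical outputs.  Planted effects couple platforms: a gene carrying
both a copy-number and an expression effect is amplified and overexpressed
in the same carrier samples, and expression/genotype effects multiply the
hazard of their carriers, so each planted item maps to one detectable
downstream signal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methylation_mirna import beta_value

GENE_SPAN = 10_000  # bp per gene slot on the synthetic chromosome
CHROM = "chr1"


class ConfigurationError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass
class SurvivalModel:
    """Exponential proportional-hazards survival model.

    baseline_hazard: events per month for a linear predictor of zero
    (default 0.05/month, i.e. a ~14-month median, typical of glioblastoma).
    censoring_rate: probability of independent censoring before the event.
    horizon: administrative censoring time in months.
    """

    baseline_hazard: float = 0.05
    censoring_rate: float = 0.2
    horizon: float = 60.0


@dataclass
class PlateLayout:
    rows: int = 16
    cols: int = 24
    replicates: int = 3


@dataclass
class PlantedEffect:
    """One planted signal.

    platform "expression": carriers overexpress the gene by
    ``expression_factor`` and their hazard is multiplied by ``effect_size``
    (a hazard ratio).  platform "cn": carriers get a copy-number segment over
    the gene with mean log-ratio ``effect_size``.  platform "snp": a marker
    whose minor-allele carriers have hazard multiplied by ``effect_size``.
    """

    gene: str
    platform: str  # expression | snp | cn
    effect_size: float
    carrier_fraction: float = 0.4
    expression_factor: float = 4.0


@dataclass
class CohortConfig:
    n_tumor: int = 200
    n_control: int = 10
    n_genes: int = 30
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exon_noise_sd: float = 10.0
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.15, 0.5)
    n_markers: int = 60
    cn_probes_per_gene: int = 2
    cn_flank_probes: int = 10
    cn_noise_sd: float = 0.25
    n_cn_controls: int = 10
    n_mirnas: int = 30
    methylation_probes_per_gene: int = 3
    plate_layout: PlateLayout = field(default_factory=PlateLayout)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tumor", "n_control", "n_genes", "n_markers", "n_cn_controls",
                     "n_mirnas", "cn_probes_per_gene", "cn_flank_probes",
                     "methylation_probes_per_gene"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.transcripts_per_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError("transcripts_per_gene must be a positive (low, high) range")
        if self.exon_noise_sd < 0:
            raise ConfigurationError("exon_noise_sd must be nonnegative")
        if self.cn_noise_sd < 0:
            raise ConfigurationError("cn_noise_sd must be nonnegative")
        sm = self.survival_model
        if sm.baseline_hazard <= 0:
            raise ConfigurationError("survival_model.baseline_hazard must be positive")
        if not 0 <= sm.censoring_rate <= 1:
            raise ConfigurationError("survival_model.censoring_rate must be in [0, 1]")
        if sm.horizon <= 0:
            raise ConfigurationError("survival_model.horizon must be positive")
        if not (0 <= self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 <= low <= high <= 0.5")
        pl = self.plate_layout
        if pl.rows <= 0 or pl.cols <= 0 or pl.replicates <= 0:
            raise ConfigurationError("plate_layout fields must be positive")
        genes = {f"G{i + 1:03d}" for i in range(self.n_genes)}
        for eff in self.planted_effects:
            if eff.platform not in ("expression", "snp", "cn"):
                raise ConfigurationError(f"planted_effects.platform invalid: {eff.platform!r}")
            if eff.effect_size <= 0 and eff.platform in ("expression", "snp"):
                raise ConfigurationError("planted_effects.effect_size (hazard ratio) must be > 0")
            if eff.gene not in genes:
                raise ConfigurationError(f"planted_effects.gene unknown: {eff.gene!r}")
            if not 0 < eff.carrier_fraction < 1:
                raise ConfigurationError("planted_effects.carrier_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    transcript_expression: dict  # gene -> baseline true transcript vector
    carriers: dict  # gene -> list of carrier tumor sample ids
    aberrant_segments: list  # dicts: sample, chrom, start, end, true_mean
    survival_effect_genes: dict  # gene or marker -> hazard ratio
    hit_wells: list  # dicts: plate, row, col, spike
    mirna_de: list  # planted differentially expressed miRNAs


@dataclass
class Cohort:
    config: CohortConfig
    annotation: pd.DataFrame
    exon_matrix: pd.DataFrame
    gene_matrix: pd.DataFrame
    sample_roles: pd.Series
    clinical: pd.DataFrame
    cn_probes: pd.DataFrame
    cn_control_probes: pd.DataFrame
    genotype_calls: pd.DataFrame
    genotype_prob: pd.DataFrame
    sample_snr: pd.Series
    marker_genes: pd.Series
    methylation: pd.DataFrame
    mirna_matrix: pd.DataFrame
    mirna_targets: pd.DataFrame
    plates: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, outdir) -> None:
        """Write all platform tables as TSV plus ground-truth JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        from .annotation import write_annotation

        write_annotation(self.annotation, out / "annotation.tsv", fmt="tsv")
        self.exon_matrix.to_csv(out / "exon_matrix.tsv", sep="\t", index_label="exon_id")
        self.gene_matrix.to_csv(out / "gene_matrix.tsv", sep="\t", index_label="gene_id")
        self.sample_roles.rename("role").to_csv(out / "sample_roles.tsv", sep="\t", index_label="sample")
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index_label="patient_id")
        self.cn_probes.to_csv(out / "cn_probes.tsv", sep="\t", index=False)
        self.cn_control_probes.to_csv(out / "cn_controls.tsv", sep="\t", index=False)
        self.genotype_calls.to_csv(out / "genotype_calls.tsv", sep="\t", index_label="marker")
        self.genotype_prob.to_csv(out / "genotype_prob.tsv", sep="\t", index_label="marker")
        self.sample_snr.rename("snr").to_csv(out / "sample_snr.tsv", sep="\t", index_label="sample")
        self.marker_genes.rename("gene").to_csv(out / "marker_genes.tsv", sep="\t", index_label="marker")
        self.methylation.to_csv(out / "methylation.tsv", sep="\t", index=False)
        self.mirna_matrix.to_csv(out / "mirna_matrix.tsv", sep="\t", index_label="mirna")
        self.mirna_targets.to_csv(out / "mirna_targets.tsv", sep="\t", index=False)
        self.plates.to_csv(out / "plates.tsv", sep="\t", index=False)
        gt = asdict(self.ground_truth)
        gt["transcript_expression"] = {g: list(map(float, v)) for g, v in gt["transcript_expression"].items()}
        (out / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))


def load_cohort(path) -> Cohort:
    """Read a cohort directory written by :meth:`Cohort.write`.

    The ground-truth JSON is loaded when present (empty otherwise), so the
    loader also works on externally supplied data laid out in the same TSV
    formats.
    """
    p = Path(path)
    from .annotation import read_annotation

    def read_indexed(name, index_col):
        return pd.read_csv(p / name, sep="\t", index_col=index_col)

    gt = GroundTruth({}, {}, [], {}, [], [])
    gt_path = p / "ground_truth.json"
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        gt = GroundTruth(
            transcript_expression={g: np.asarray(v) for g, v in raw.get("transcript_expression", {}).items()},
            carriers=raw.get("carriers", {}),
            aberrant_segments=raw.get("aberrant_segments", []),
            survival_effect_genes=raw.get("survival_effect_genes", {}),
            hit_wells=raw.get("hit_wells", []),
            mirna_de=raw.get("mirna_de", []),
        )
    plates = pd.read_csv(p / "plates.tsv", sep="\t", keep_default_na=False, na_values=[""])
    plates["sirna"] = plates["sirna"].fillna("")
    plates["gene"] = plates["gene"].fillna("")
    return Cohort(
        config=CohortConfig(),
        annotation=read_annotation(p / "annotation.tsv", fmt="tsv"),
        exon_matrix=read_indexed("exon_matrix.tsv", "exon_id"),
        gene_matrix=read_indexed("gene_matrix.tsv", "gene_id"),
        sample_roles=read_indexed("sample_roles.tsv", "sample")["role"],
        clinical=read_indexed("clinical.tsv", "patient_id"),
        cn_probes=pd.read_csv(p / "cn_probes.tsv", sep="\t"),
        cn_control_probes=pd.read_csv(p / "cn_controls.tsv", sep="\t"),
        genotype_calls=read_indexed("genotype_calls.tsv", "marker"),
        genotype_prob=read_indexed("genotype_prob.tsv", "marker"),
        sample_snr=read_indexed("sample_snr.tsv", "sample")["snr"],
        marker_genes=read_indexed("marker_genes.tsv", "marker")["gene"],
        methylation=pd.read_csv(p / "methylation.tsv", sep="\t"),
        mirna_matrix=read_indexed("mirna_matrix.tsv", "mirna"),
        mirna_targets=pd.read_csv(p / "mirna_targets.tsv", sep="\t"),
        plates=plates,
        ground_truth=gt,
    )


def generate_survival(
    linear_predictor, model: SurvivalModel, rng: np.random.Generator, patient_ids=None
) -> pd.DataFrame:
    """Survival records from exponential proportional hazards.

    Event times are exponential with hazard ``baseline * exp(predictor)``;
    with probability ``censoring_rate`` a patient is independently censored
    at a uniform fraction of the event time, and everyone still under
    observation at the horizon is censored there.  Indicator 1 = death,
    0 = censored.
    """
    if model.baseline_hazard <= 0:
        raise ConfigurationError("survival_model.baseline_hazard must be positive")
    lp = np.asarray(linear_predictor, dtype=float)
    hazard = model.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    months = t_event.copy()
    event = np.ones(lp.size, dtype=int)
    censored = rng.random(lp.size) < model.censoring_rate
    months[censored] = rng.uniform(0, t_event[censored])
    event[censored] = 0
    late = months > model.horizon
    months[late] = model.horizon
    event[late] = 0
    if patient_ids is None:
        patient_ids = [f"P{i + 1:04d}" for i in range(lp.size)]
    return pd.DataFrame({"months": months, "event": event}, index=pd.Index(patient_ids, name="patient_id"))


def _gene_structures(config: CohortConfig, rng: np.random.Generator):
    """Annotation rows and per-gene incidence/baseline structures."""
    lo, hi = config.transcripts_per_gene
    ann_rows = []
    structures = {}
    for i in range(config.n_genes):
        gene = f"G{i + 1:03d}"
        n_t = int(rng.integers(lo, hi + 1))
        n_shared = 2
        n_e = n_t + n_shared
        gene_start = config.cn_flank_probes * 500 + i * GENE_SPAN + 1000
        a = np.zeros((n_e, n_t))
        a[:n_t, :n_t] = np.eye(n_t)  # private exons guarantee full column rank
        a[n_t:, :] = 1.0  # shared exons belong to every transcript
        exon_ids = [f"{gene}_E{j + 1}" for j in range(n_e)]
        baseline = rng.uniform(50.0, 150.0, size=n_t)
        for k in range(n_t):
            transcript = f"{gene}_T{k + 1}"
            member_exons = [j for j in range(n_e) if a[j, k] == 1.0]
            for j in member_exons:
                ann_rows.append(
                    {
                        "gene_id": gene,
                        "transcript_id": transcript,
                        "exon_id": exon_ids[j],
                        "chrom": CHROM,
                        "start": gene_start + j * 200,
                        "end": gene_start + j * 200 + 100,
                        "strand": "+",
                    }
                )
        structures[gene] = {"A": a, "exon_ids": exon_ids, "baseline": baseline,
                            "start": gene_start, "end": gene_start + n_e * 200}
    return pd.DataFrame(ann_rows), structures


def _plates(config: CohortConfig, rng: np.random.Generator, hit_gene: str):
    """Two assay plates (proliferation, caspase) with polynomial background."""
    pl = config.plate_layout
    screen_genes = [hit_gene] + [f"SG{i:02d}" for i in range(1, 11)]
    rows = []
    hit_wells = []
    for assay in ("proliferation", "caspase"):
        plate_id = f"{assay}_p1"
        # low-order polynomial spatial background (what degree-2 LOESS removes)
        b = rng.uniform(-1, 1, size=6)
        wells = []
        for r in range(pl.rows):
            for c in range(pl.cols):
                wells.append((r, c))
        sirna_wells = []
        for g in screen_genes:
            for s in range(1, 5):
                for rep in range(pl.replicates):
                    sirna_wells.append((f"{g}_{s}", g))
        idx = 0
        for r, c in wells:
            background = 1000 + 20 * (b[0] + b[1] * r / pl.rows + b[2] * c / pl.cols
                                      + b[3] * (r / pl.rows) ** 2
                                      + b[4] * (r / pl.rows) * (c / pl.cols)
                                      + b[5] * (c / pl.cols) ** 2)
            noise = rng.normal(0, 15)
            if c == 0:
                role, sirna, gene, signal = "negative", "siNEG", "", background + noise
            elif c == 1:
                role, sirna, gene, signal = "death", "siDEATH", "", background * 0.2 + noise
            elif idx < len(sirna_wells):
                sirna, gene = sirna_wells[idx]
                idx += 1
                role = "sample"
                signal = background + noise
                # the hit gene's first two siRNAs inhibit strongly in the
                # proliferation assay and activate in the caspase assay
                if gene == hit_gene and sirna.endswith(("_1", "_2")):
                    spike = -400 if assay == "proliferation" else 400
                    signal += spike
                    hit_wells.append({"plate": plate_id, "row": r, "col": c, "spike": float(spike)})
            else:
                role, sirna, gene, signal = "empty", "", "", np.nan
            rows.append(
                {"plate": plate_id, "assay": assay, "row": r, "col": c, "signal": signal,
                 "role": role, "sirna": sirna, "gene": gene}
            )
    return pd.DataFrame(rows), hit_wells


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate all platform tables, clinical records and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tumor_ids = [f"T{i + 1:04d}" for i in range(config.n_tumor)]
    control_ids = [f"C{i + 1:03d}" for i in range(config.n_control)]
    samples = tumor_ids + control_ids
    roles = pd.Series(["tumor"] * config.n_tumor + ["control"] * config.n_control,
                      index=pd.Index(samples, name="sample"), name="role")

    annotation, structures = _gene_structures(config, rng)
    genes = list(structures)

    # --- carriers for expression/cn effects (shared per gene to couple platforms)
    effects_by_gene: dict[str, list[PlantedEffect]] = {}
    for eff in config.planted_effects:
        effects_by_gene.setdefault(eff.gene, []).append(eff)
    carriers: dict[str, np.ndarray] = {}
    for gene, effs in effects_by_gene.items():
        if any(e.platform in ("expression", "cn") for e in effs):
            frac = max(e.carrier_fraction for e in effs)
            n_carr = int(round(frac * config.n_tumor))
            carriers[gene] = rng.choice(config.n_tumor, size=n_carr, replace=False)

    # --- expression: per-sample true transcripts, exon matrix e = A t + noise
    exon_blocks, gene_rows = [], []
    truth_t = {}
    for gene in genes:
        st = structures[gene]
        n_t = st["A"].shape[1]
        t_mat = np.tile(st["baseline"][:, None], (1, len(samples)))
        for eff in effects_by_gene.get(gene, []):
            if eff.platform == "expression":
                t_mat[:, carriers[gene]] *= eff.expression_factor
        e = st["A"] @ t_mat
        if config.exon_noise_sd > 0:
            e = e + rng.normal(0, config.exon_noise_sd, size=e.shape)
        exon_blocks.append(pd.DataFrame(e, index=st["exon_ids"], columns=samples))
        g = t_mat.sum(axis=0)
        if config.exon_noise_sd > 0:
            g = g + rng.normal(0, config.exon_noise_sd, size=g.shape)
        gene_rows.append(pd.Series(g, index=samples, name=gene))
        truth_t[gene] = st["baseline"]
    exon_matrix = pd.concat(exon_blocks)
    exon_matrix.index.name = "exon_id"
    gene_matrix = pd.DataFrame(gene_rows)
    gene_matrix.index.name = "gene_id"

    # --- genotypes (Hardy-Weinberg at drawn MAFs); planted markers first
    snp_effects = [e for e in config.planted_effects if e.platform == "snp"]
    marker_ids = [f"M_{e.gene}" for e in snp_effects]
    marker_gene_list = [e.gene for e in snp_effects]
    n_null = config.n_markers - len(marker_ids)
    for i in range(n_null):
        marker_ids.append(f"M{i + 1:04d}")
        marker_gene_list.append(genes[i % len(genes)])
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=len(marker_ids))
    probs = np.column_stack([(1 - mafs) ** 2, 2 * mafs * (1 - mafs), mafs**2])
    draws = rng.random((len(marker_ids), config.n_tumor))
    geno_code = (draws[:, :] > probs[:, [0]]).astype(int) + (draws > (probs[:, [0]] + probs[:, [1]])).astype(int)
    marker_index = pd.Index(marker_ids, name="marker")
    calls = pd.DataFrame(np.array(["AA", "AB", "BB"])[geno_code], index=marker_index, columns=tumor_ids)
    prob = pd.DataFrame(
        np.where(rng.random(geno_code.shape) < 0.02, 0.80, 0.99), index=marker_index, columns=tumor_ids
    )
    snr = pd.Series(rng.normal(10, 2, size=config.n_tumor),
                    index=pd.Index(tumor_ids, name="sample"), name="snr")
    marker_genes = pd.Series(marker_gene_list, index=marker_index, name="gene")

    # --- survival: hazards from planted expression + SNP effects
    lp = np.zeros(config.n_tumor)
    survival_effect_genes = {}
    for eff in config.planted_effects:
        if eff.platform == "expression":
            lp[carriers[eff.gene]] += np.log(eff.effect_size)
            survival_effect_genes[eff.gene] = eff.effect_size
        elif eff.platform == "snp":
            risk = calls.loc[f"M_{eff.gene}"].isin(["AB", "BB"]).to_numpy()
            lp[risk] += np.log(eff.effect_size)
            survival_effect_genes[f"M_{eff.gene}"] = eff.effect_size
    clinical = generate_survival(lp, config.survival_model, rng, patient_ids=tumor_ids)

    # --- copy number: probe grid, planted segments for cn effects
    step = GENE_SPAN // config.cn_probes_per_gene
    n_probes = 2 * config.cn_flank_probes + config.n_genes * config.cn_probes_per_gene
    pos = np.arange(n_probes) * step
    aberrant_segments = []
    cn_rows = []
    for si, sample in enumerate(tumor_ids):
        mu = np.zeros(n_probes)
        for gene, effs in effects_by_gene.items():
            for eff in effs:
                if eff.platform == "cn" and si in carriers[gene]:
                    st = structures[gene]
                    lo = st["start"] - 2 * step
                    hi = st["end"] + 2 * step
                    inside = (pos >= lo) & (pos <= hi)
                    mu[inside] = eff.effect_size
                    aberrant_segments.append(
                        {"sample": sample, "chrom": CHROM,
                         "start": int(pos[inside][0]), "end": int(pos[inside][-1]) + 1,
                         "true_mean": float(eff.effect_size)}
                    )
        lr = mu + rng.normal(0, config.cn_noise_sd, size=n_probes)
        cn_rows.append(pd.DataFrame({"sample": sample, "chrom": CHROM, "pos": pos, "logratio": lr}))
    cn_probes = pd.concat(cn_rows, ignore_index=True)
    ctl_rows = []
    for j in range(config.n_cn_controls):
        lr = rng.normal(0, config.cn_noise_sd, size=n_probes)
        ctl_rows.append(pd.DataFrame({"sample": f"B{j + 1:03d}", "chrom": CHROM, "pos": pos, "logratio": lr}))
    cn_controls = pd.concat(ctl_rows, ignore_index=True)

    # --- methylation: per-gene promoter probes, M/U channels
    meth_rows = []
    gene_beta = rng.beta(2, 2, size=len(genes))
    for gi, gene in enumerate(genes):
        for p in range(config.methylation_probes_per_gene):
            total = rng.uniform(1000, 4000, size=config.n_tumor)
            b = np.clip(gene_beta[gi] + rng.normal(0, 0.03, size=config.n_tumor), 0, 1)
            m_sig = total * b
            meth_rows.append(
                pd.DataFrame(
                    {"probe": f"{gene}_cg{p + 1}", "gene": gene, "sample": tumor_ids,
                     "M": m_sig, "U": total - m_sig}
                )
            )
    methylation = pd.concat(meth_rows, ignore_index=True)

    # --- miRNA: null matrix with two planted 4-fold miRNAs, synthetic targets
    mirna_ids = [f"mir-{i + 1:03d}" for i in range(config.n_mirnas)]
    base = rng.uniform(50, 150, size=config.n_mirnas)
    mir = np.tile(base[:, None], (1, len(samples))) + rng.normal(0, 10, size=(config.n_mirnas, len(samples)))
    planted_mirnas = mirna_ids[:2]
    for mi in range(2):
        mir[mi, : config.n_tumor] += 3 * base[mi]  # 4-fold in tumors
    mirna_matrix = pd.DataFrame(mir, index=pd.Index(mirna_ids, name="mirna"), columns=samples)
    tgt_rows = []
    for mi, mirna in enumerate(mirna_ids):
        for gene in rng.choice(genes, size=int(rng.integers(1, 4)), replace=False):
            p = 10 ** rng.uniform(-8, -2)
            tgt_rows.append({"mirna": mirna, "gene": gene, "p": p})
    mirna_targets = pd.DataFrame(tgt_rows)

    plates, hit_wells = _plates(config, rng, hit_gene="MSN")

    truth = GroundTruth(
        transcript_expression=truth_t,
        carriers={g: [tumor_ids[i] for i in sorted(c)] for g, c in carriers.items()},
        aberrant_segments=aberrant_segments,
        survival_effect_genes=survival_effect_genes,
        hit_wells=hit_wells,
        mirna_de=planted_mirnas,
    )
    return Cohort(
        config=config,
        annotation=annotation,
        exon_matrix=exon_matrix,
        gene_matrix=gene_matrix,
        sample_roles=roles,
        clinical=clinical,
        cn_probes=cn_probes,
        cn_control_probes=cn_controls,
        genotype_calls=calls,
        genotype_prob=prob,
        sample_snr=snr,
        marker_genes=marker_genes,
        methylation=methylation,
        mirna_matrix=mirna_matrix,
        mirna_targets=mirna_targets,
        plates=plates,
        ground_truth=truth,
    )
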