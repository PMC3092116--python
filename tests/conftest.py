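import numpy as np
import pandas as pd
import pytest

from gbmpipe.synthetic import CohortConfig, PlantedEffect, generate_cohort


def make_models(spec: dict[str, dict[str, list[str]]]) -> pd.DataFrame:
    """Annotation frame from {gene: {transcript: [exon ids]}} with synthetic coordinates."""
    rows = []
    for gene, transcripts in spec.items():
        exon_pos = {}
        for exons in transcripts.values():
            for e in exons:
                exon_pos.setdefault(e, 1000 + 200 * len(exon_pos))
        for tid, exons in transcripts.items():
            for e in exons:
                rows.append(
                    {
                        "gene_id": gene,
                        "transcript_id": tid,
                        "exon_id": e,
                        "chrom": "chr1",
                        "start": exon_pos[e],
                        "end": exon_pos[e] + 100,
                        "strand": "+",
                    }
                )
    return pd.DataFrame(rows)


def clinical_frame(times, events) -> pd.DataFrame:
    ids = [f"P{i}" for i in range(len(times))]
    return pd.DataFrame({"months": times, "event": events}, index=pd.Index(ids, name="patient_id"))


@pytest.fixture(scope="session")
def small_cohort():
    """Small tumor/control cohort with one coupled expression+CN effect and one SNP effect."""
    cfg = CohortConfig(
        n_tumor=120,
        n_genes=10,
        n_markers=20,
        seed=7,
        planted_effects=[
            PlantedEffect(gene="G003", platform="expression", effect_size=3.0),
            PlantedEffect(gene="G003", platform="cn", effect_size=1.0),
            PlantedEffect(gene="G007", platform="snp", effect_size=2.5),
        ],
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects (for false-positive-rate checks)."""
    return generate_cohort(CohortConfig(n_tumor=80, n_genes=8, n_markers=15, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
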