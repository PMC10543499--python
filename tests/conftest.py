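import numpy as np
import pandas as pd
import pytest

import insuclust as ic


def make_stats(records):
    """Long-format summary statistics from (vid, chrom, pos, ea, oa, beta, se, p, trait)."""
    rows = []
    for vid, chrom, pos, ea, oa, beta, se, p, trait in records:
        rows.append(
            dict(
                variant_id=vid,
                chromosome=chrom,
                position=pos,
                effect_allele=ea,
                other_allele=oa,
                effect_allele_frequency=0.3,
                beta=beta,
                standard_error=se,
                p_value=p,
                sample_size=1000,
                trait=trait,
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def sumstats_a():
    """The SUMSTATS-A fixture: stats table plus planted truth."""
    cfg = ic.SUMSTATS_A()
    stats, truth = ic.generate_summary_stats(cfg)
    return cfg, stats, truth


@pytest.fixture(scope="session")
def sumstats_a_matrix(sumstats_a):
    """Non-negative matrix built from SUMSTATS-A through the full input pipeline."""
    _, stats, _ = sumstats_a
    variants = ic.select_variants(stats, "FI")
    zmat = ic.prune_traits(ic.align_to_risk_allele(stats, variants, "FI"))
    return ic.build_nonnegative_matrix(zmat)


@pytest.fixture(scope="session")
def cohort_a():
    """The COHORT-A fixture: config, cluster definitions, panel and phenotypes."""
    cfg = ic.COHORT_A()
    _, truth = ic.generate_summary_stats(cfg)
    defs = ic.planted_cluster_definitions(truth)
    panel, cohort = ic.generate_cohort(cfg, defs, seed=cfg.seed)
    return cfg, defs, panel, cohort


@pytest.fixture(scope="session")
def cohort_a_scores(cohort_a):
    cfg, defs, panel, cohort = cohort_a
    ld = ic.generate_ld_reference(cfg, variant_ids=defs.all_variant_ids())
    resolved = ic.resolve_variants(defs, panel, ld)
    return ic.compute_pps(panel, resolved)


def small_panel(dosages, alleles, individuals=None):
    """GenotypePanel from a dict of variant -> (effect, other) and a dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    variants = pd.DataFrame(
        [
            dict(variant_id=vid, chromosome=1, position=100 + i, effect_allele=ea, other_allele=oa)
            for i, (vid, (ea, oa)) in enumerate(alleles.items())
        ]
    ).set_index("variant_id")
    if individuals is None:
        individuals = [f"I{i}" for i in range(dosages.shape[0])]
    return ic.GenotypePanel.from_dosages(individuals, variants, dosages)


def make_defs(rows, cutoff=0.0):
    """ClusterDefinitions from (cluster, variant_id, fi_allele, weight) rows."""
    frame = pd.DataFrame(
        rows, columns=["cluster", "variant_id", "fi_increasing_allele", "weight"]
    )
    return ic.ClusterDefinitions(
        variant_weights=frame,
        trait_weights=pd.DataFrame(columns=["cluster", "trait", "signed_weight"]),
        cutoff=cutoff,
    )
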