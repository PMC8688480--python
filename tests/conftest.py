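import numpy as np
import pytest
from scipy import stats

from targetmr.summary_data import (BINARY, QUANTITATIVE, GeneAnnotation,
                                   InstrumentSet, LdMatrix, VariantAssociation)
from targetmr.synthetic_data import (SimulationConfig, SuiteConfig,
                                     generate_scenario_suite)

GENE = GeneAnnotation("GENE1", "G1", "1", 1_000_000, 1_030_000)


def assoc(variant_id="rs1", beta=0.1, se=0.05, trait="GENE1", *, chrom="1",
          pos=1_000_100, ea="A", oa="G", eaf=0.3, n=10_000.0, n_cases=None,
          n_controls=None, trait_type=QUANTITATIVE, pvalue=None):
    """Shorthand VariantAssociation with a p-value consistent with beta/se."""
    if pvalue is None:
        pvalue = float(np.clip(2 * stats.norm.sf(abs(beta / se)), 1e-320, 1.0))
    return VariantAssociation(variant_id, chrom, pos, ea, oa, beta, se, pvalue,
                              trait, eaf=eaf, n=n, n_cases=n_cases,
                              n_controls=n_controls, trait_type=trait_type)


def make_instruments(bx, sx, by, sy, rho=None, gene=GENE, outcome="OUT",
                     binary=False, tissue="blood"):
    """InstrumentSet from plain arrays (already harmonized by construction)."""
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    J = len(bx)
    ids = [f"rs{j + 1}" for j in range(J)]
    if rho is None:
        rho = np.eye(J)
    exp = [assoc(ids[j], float(bx[j]), float(sx[j]), gene.gene_id,
                 pos=gene.start + 100 * j) for j in range(J)]
    if binary:
        out = [assoc(ids[j], float(by[j]), float(sy[j]), outcome,
                     pos=gene.start + 100 * j, n=None, n_cases=5_000.0,
                     n_controls=5_000.0, trait_type=BINARY) for j in range(J)]
    else:
        out = [assoc(ids[j], float(by[j]), float(sy[j]), outcome,
                     pos=gene.start + 100 * j) for j in range(J)]
    return InstrumentSet(gene, exp, out, LdMatrix(ids, np.asarray(rho, float)),
                         tissue)


def ar1(J, decay):
    idx = np.arange(J)
    return decay ** np.abs(idx[:, None] - idx[None, :])


@pytest.fixture(scope="session")
def small_suite():
    """Scaled-down scenario suite for pipeline unit tests."""
    cfg = SuiteConfig(n_null=20, n_causal=3, n_pleiotropic=1, n_linkage=1,
                      n_reverse=1, sim=SimulationConfig(n_snps_per_region=40))
    return generate_scenario_suite(11, cfg)


@pytest.fixture(scope="session")
def small_result(small_suite):
    from targetmr.pipeline import StudyConfig, StudyData, run_full_study
    data = StudyData.from_suite(small_suite)
    cfg = StudyConfig(seed=11, tissues=("blood", "brain"),
                      progression_outcomes=("prog_motor",))
    return run_full_study(data, cfg)
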