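import numpy as np
import pytest

import ecgmr


@pytest.fixture(scope="session")
def pr_cohort():
    """A mid-sized PR-interval-like cohort shared across read-only tests."""
    cfg = ecgmr.pr_interval_scenario(n_individuals=50_000, seed=11)
    return ecgmr.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def pr_score(pr_cohort):
    weights = {v.id: v.beta_exposure for v in pr_cohort.variants}
    return ecgmr.build_score(pr_cohort.genotypes, weights, pr_cohort.variant_ids)


@pytest.fixture(scope="session")
def pr_pairs(pr_cohort):
    return ecgmr.make_summary_pair(pr_cohort, split_fraction=0.5, seed=13)


def make_variant(vid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                 beta=1.0, se=0.1, p=1e-10, gene=None):
    return ecgmr.VariantRecord(
        id=vid, chromosome=chrom, position=pos, effect_allele=ea,
        other_allele=oa, eaf=eaf, beta_exposure=beta, se_exposure=se,
        p_exposure=p, gene_annotation=gene,
    )


def make_pair(beta_x=1.0, beta_y=0.5, se_x=0.05, se_y=0.1, vid="rs1", **kw):
    v = make_variant(vid=vid, beta=beta_x, se=se_x, **kw)
    return ecgmr.SummaryPair(variant=v, beta_outcome=beta_y, se_outcome=se_y,
                             harmonised=True)
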