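import numpy as np
import pandas as pd
import pytest

import cgiscreen as cg
from cgiscreen.fitness import compute_guide_lfc, depth_normalize, gene_level_lfc


@pytest.fixture(scope="session")
def toy_library() -> cg.LibraryDefinition:
    return cg.LibraryDefinition(
        pd.DataFrame(
            {
                "guide_id": ["GA_g1", "GA_g2", "GA_g3", "GB_g1", "GB_g2", "GB_g3"],
                "gene": ["GA"] * 3 + ["GB"] * 3,
            }
        )
    )


@pytest.fixture(scope="session")
def toy_sheet() -> cg.SampleSheet:
    rows = [{"sample_id": "T0", "condition": "DMSO", "timepoint": 0, "replicate": "pool"}]
    for cond in ("DMSO", "CPT"):
        for tp in (6, 12):
            for rep in ("A", "B"):
                rows.append(
                    {
                        "sample_id": f"{cond}_T{tp}_{rep}",
                        "condition": cond,
                        "timepoint": tp,
                        "replicate": rep,
                    }
                )
    return cg.SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def twofold_down():
    """Full-design fixture: one gene's treated counts halved at every timepoint."""
    counts, sheet, lib, truth = cg.twofold_preset(seed=11, factor=0.5)
    results = cg.score_screens(counts, sheet, lib)
    return counts, sheet, lib, truth, results


@pytest.fixture(scope="session")
def twofold_up():
    counts, sheet, lib, truth = cg.twofold_preset(seed=11, factor=2.0)
    results = cg.score_screens(counts, sheet, lib)
    return counts, sheet, lib, truth, results


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions: 1011 genes, triplicates, 50 planted CGI genes."""
    cfg = cg.preset_config("default", seed=7)
    counts, sheet, lib, truth = cg.simulate_screen(cfg)
    results = cg.score_screens(counts, sheet, lib)
    gene_fitness = gene_level_lfc(
        compute_guide_lfc(depth_normalize(counts), sheet), lib
    ).lfc
    report = cg.recovery_report(truth, results.gene_table, gene_fitness=gene_fitness)
    return truth, results, report


@pytest.fixture(scope="session")
def null_sim():
    """Same design with no planted chemical-genetic effects."""
    cfg = cg.preset_config("null", seed=7)
    counts, sheet, lib, truth = cg.simulate_screen(cfg)
    results = cg.score_screens(counts, sheet, lib)
    report = cg.recovery_report(truth, results.gene_table)
    return truth, results, report
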