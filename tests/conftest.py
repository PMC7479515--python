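"""Shared synthetic fixtures.

The cohort fixtures are session-scoped because several modules test recovery
against the same planted truth; all generation is seeded and deterministic.
"""

import numpy as np
import pandas as pd
import pytest

from scprograms import classify, cna, preprocess, scoring, synth


@pytest.fixture(scope="session")
def genome():
    """2000-gene genome with program, cycling, and normal-marker modules."""
    return synth.make_genome(
        2000,
        10,
        {
            "P1": 30,
            "P2": 30,
            "P3": 30,
            "S": 30,
            "G2M": 30,
            "microglia": 20,
            "oligodendrocyte": 20,
            "t_cell": 20,
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort(genome):
    """3 samples x 300 cells: 80% malignant over 3 programs with arm gains
    (chr1q x1.5) and losses (chr3p x0.5), 20% normal cells, 15% cycling."""
    design = [
        synth.SampleDesign(
            f"S{i}",
            "PF",
            malignant={"P1": 80, "P2": 80, "P3": 80},
            normal={"microglia": 25, "oligodendrocyte": 20, "t_cell": 15},
            cna_events=[("chr1", "q", 1.5), ("chr3", "p", 0.5)],
            cycling_fraction=0.15,
        )
        for i in range(3)
    ]
    m, truth, ann = synth.simulate_cells(genome, design, seed=12)
    return m, truth, ann


@pytest.fixture(scope="session")
def cohort_pipeline(cohort):
    """Preprocessed views of the cohort: E, Ea, Er, CNA profile and calls."""
    m, truth, ann = cohort
    e = preprocess.log_transform(m)
    ea = preprocess.aggregate_expression(m)
    er = preprocess.center_expression(e)
    profile = cna.compute_cna_profile(er, cna.order_genes(ann))
    normal_cells = truth.index[truth["cell_class"] != "malignant"]
    reference = profile.window_values.loc[normal_cells]
    calls = cna.call_cna_by_sample(profile, truth["sample_id"], reference)
    return {
        "E": e,
        "Ea": ea,
        "Er": er,
        "profile": profile,
        "reference": reference,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def null_cohort():
    """Null configuration: one module at fold 1, Poisson counts, no CNA."""
    g = synth.make_genome(1500, 8, {"P0": 30}, seed=7)
    m, truth, _ = synth.simulate_cells(
        g,
        [synth.SampleDesign("S0", "PF", malignant={"P0": 300})],
        noise=synth.NoiseParams(dispersion=0.0),
        seed=8,
        fold_change=1.0,
    )
    er = preprocess.center_expression(preprocess.log_transform(m))
    ea = preprocess.aggregate_expression(m)
    return g, er, ea


def brute_force_sc(er_values: pd.DataFrame, signature, control_map) -> pd.Series:
    """Independent two-mean score: loops, no shared code with the scorer."""
    out = {}
    for cell in er_values.index:
        sig_vals = [er_values.at[cell, g] for g in signature]
        ctrl_vals = []
        for g in signature:
            ctrl_vals.extend(er_values.at[cell, c] for c in control_map[g])
        out[cell] = float(np.mean(sig_vals)) - float(np.mean(ctrl_vals))
    return pd.Series(out)
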