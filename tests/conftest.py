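import numpy as np
import pytest

import peaquant as pq


@pytest.fixture(scope="session")
def panel():
    return pq.PanelConfig(
        "demo",
        tuple(pq.AssayDefinition(a) for a in ("IL6", "NTproBNP", "GDF15")),
    )


@pytest.fixture(scope="session")
def zero_noise_truth(panel):
    return pq.default_panel_truth(panel, ct_noise_sd=0.0)


@pytest.fixture(scope="session")
def dilution_series(panel, zero_noise_truth):
    """Neat-scale two-fold dilution series around each assay's inflection."""
    tmap = {t.assay_id: t for t in zero_noise_truth}
    return {
        a.assay_id: tmap[a.assay_id].fourpl[2]
        * a.predilution_factor
        * 2.0 ** (np.arange(12) - 6.0)
        for a in panel.assays
    }


def make_zero_noise_pipeline(panel, truth, sample_concs, n_plates=2, seed=5):
    """simulate -> normalize -> fit curves; returns (npx, truth_df, curves)."""
    table, truth_df = pq.simulate_plates(
        panel, truth, n_plates, len(next(iter(sample_concs.values()))),
        run_offsets=0.0, seed=seed, sample_concs=sample_concs,
    )
    npx = pq.normalize_plates(table)
    curves = {}
    for aid in panel.assay_ids:
        conc, ny = pq.extract_standards(npx.values, truth_df, aid)
        cv = pq.fit_4pl(conc, ny, assay_id=aid)
        blanks = ny[conc == 0]
        cv = pq.determine_lod(cv, blanks, predilution=panel.assay(aid).predilution_factor)
        cv = pq.determine_loq(cv, conc, ny, predilution=panel.assay(aid).predilution_factor)
        curves[aid] = cv
    return npx, truth_df, curves
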