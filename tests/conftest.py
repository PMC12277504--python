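import dataclasses

import pytest

from cdld import evaluation as ev
from cdld import model as mdl
from cdld import preprocessing as prep
from cdld import synthetic_data as sim

# small model for unit tests: same architecture family, minutes -> seconds
SMALL_MODEL = mdl.ModelConfig(
    latent_dim=8,
    batch_size=64,
    epochs=2,
    sub_epochs=2,
    hidden_widths=(16, 8),
    head_hidden=(16,),
    learning_rate=1e-3,
    seed=0,
)

SMALL_SIM = sim.SimConfig(
    n_patients=60,
    n_providers=8,
    n_admissions=80,
    measurements_per_stay_range=(2, 6),
    seed=123,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort shared by read-only tests."""
    tables, truth = sim.generate(SMALL_SIM)
    return tables, truth


@pytest.fixture(scope="session")
def small_interactions(small_cohort):
    tables, _ = small_cohort
    table, provider_map = prep.build_interaction_table(tables)
    return table, provider_map


def full_run(sim_config, seed, model_config=None, baseline=False):
    """Simulate -> preprocess -> train -> evaluate, returning all artifacts.

    Stage seeds are derived from ``seed`` so one integer pins the whole run.
    """
    tables, truth = sim.generate(sim_config)
    table, provider_map = prep.build_interaction_table(tables)
    splits = prep.split_data(len(table), seed=seed + 100)
    augmented = prep.augment_training(
        table.iloc[splits.train_rows].reset_index(drop=True), seed=seed + 200
    )
    config = dataclasses.replace(model_config or mdl.ModelConfig(), seed=seed + 300)
    model = mdl.init_model(config, len(provider_map))
    valid = table.iloc[splits.valid_rows]
    model, curve_cyclic = mdl.cyclic_train(model, augmented.frame, valid)
    model, curve_synth = mdl.synthesize_predictor(model, augmented.frame, valid)
    report = ev.evaluate_model(model, table, splits)
    out = {
        "tables": tables,
        "truth": truth,
        "table": table,
        "provider_map": provider_map,
        "splits": splits,
        "augmented": augmented,
        "model": model,
        "curves": (curve_cyclic, curve_synth),
        "report": report,
    }
    if baseline:
        bl, _ = mdl.train_patient_only_baseline(augmented.frame, valid, config)
        out["baseline_report"] = ev.evaluate_baseline(bl, table, splits)
    return out
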