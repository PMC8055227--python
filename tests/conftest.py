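import pytest
from hypothesis import settings, HealthCheck

from hdxdiff import synthetic_fixtures as synth
from hdxdiff import uptake_core, differential

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_manifest():
    return synth.null_manifest(seed=11, n_peptides=30)


@pytest.fixture(scope="session")
def effect_manifest():
    return synth.effect_manifest(seed=12, effect_size=1.0, n_affected=10,
                                 n_peptides=30, control_state="MAX")


@pytest.fixture(scope="session")
def null_data(null_manifest):
    """(dataset, truth) from a two-state manifest with no injected effects."""
    return synth.generate_cluster_file(null_manifest)


@pytest.fixture(scope="session")
def effect_data(effect_manifest):
    return synth.generate_cluster_file(effect_manifest)


@pytest.fixture(scope="session")
def effect_pipeline(effect_data):
    """Aggregated uptake + differentials for the effect dataset."""
    dataset, truth = effect_data
    reps = uptake_core.compute_replicate_uptake(dataset)
    kept, _ = uptake_core.filter_charge_states(reps)
    uptakes = uptake_core.aggregate_uptake(kept)
    a = uptakes[uptakes["state"] == "APO"]
    b = uptakes[uptakes["state"] == "HOLO"]
    diffs = differential.uptake_difference(a, b)
    return {"dataset": dataset, "truth": truth, "replicates": kept,
            "uptakes": uptakes, "a": a, "b": b, "diffs": diffs}


@pytest.fixture()
def tiny_cluster_csv(tmp_path):
    """Hand-written 3-row cluster file: one peptide, one state, two exposures."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "Protein,Start,End,Sequence,Modification,Fragment,MaxUptake,MHP,"
        "State,Exposure,File,z,RT,Inten,Center\n"
        "PROT,1,5,AKLVG,,,4,501.3,Apo,0,rep1.raw,1,5.0,1000,501.3\n"
        "PROT,1,5,AKLVG,,,4,501.3,Apo,0.5,rep1.raw,1,5.0,900,503.7\n"
        "PROT,1,5,AKLVG,,,4,501.3,Apo,0.5,rep2.raw,1,5.0,950,503.8\n")
    return path
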