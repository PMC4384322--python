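import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mossnet import fixtures, interolog, io_formats as iof, orthology, reference_merge as rm


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """A generated synthetic world plus the full pipeline run over it."""
    out = tmp_path_factory.mktemp("world")
    spec = fixtures.WorldSpec(seed=7)
    manifest = fixtures.generate_world(spec, out)
    files = fixtures.world_files(out)
    translator = rm.build_translator([iof.read_mapping_table(files["mappings"])])
    record_sets = [
        iof.read_reference_interactions(files[f"interactions_{db}"], dialect).records
        for db, dialect in fixtures.SOURCE_DIALECTS.items()
    ]
    merged = rm.merge_interactomes(record_sets, translator)
    clusters = iof.read_inparanoid_clusters(files["clusters"], "moss")
    omap = orthology.select_one_to_one(clusters)
    prediction = interolog.predict_interologs(merged.records, omap)
    unique = interolog.deduplicate(prediction.predictions)
    return {
        "dir": out,
        "spec": spec,
        "manifest": manifest,
        "files": files,
        "translator": translator,
        "merged": merged,
        "clusters": clusters,
        "omap": omap,
        "prediction": prediction,
        "unique": unique,
    }
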