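import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_clean_run():
    """A small zero-noise, zero-decoy synthetic run through the whole
    pipeline, shared by tests that only need a realistic finished state."""
    from tagsieve import (
        MatchParams, SyntheticConfig, build_index, generate_database,
        match_tags, run_two_pass, simulate_tags,
    )
    from tagsieve.tag_store import SequenceTag, SpectrumKey, TagObservation, TagStore

    cfg = SyntheticConfig(
        n_organisms=3, proteins_per_organism=5, protein_length_range=(80, 160),
        n_spectra=300, tags_per_spectrum=1, gap_noise_sd=0.0,
        decoy_tag_fraction=0.0, distractor_proteins=40, isoform_pairs=2,
        seed=11,
    )
    records, truth = generate_database(cfg)
    table = simulate_tags(records, truth, cfg)
    store = TagStore(max_rank=cfg.tags_per_spectrum)
    for row in table.itertuples(index=False):
        store.add(TagObservation(
            SpectrumKey(row.sample, row.spectrum_id),
            SequenceTag(float(row.n_gap), row.tag_seq, float(row.c_gap)),
            int(row.rank)))
    params = MatchParams()
    index = build_index(records, params, k=cfg.tag_length)
    counts, matches = match_tags(index, store.distinct_tags(), params)
    result = run_two_pass(records, counts)
    return dict(cfg=cfg, records=records, truth=truth, table=table,
                store=store, params=params, counts=counts, matches=matches,
                result=result)
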