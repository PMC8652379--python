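import pytest

from kce import corpus_prep, splits, synth


@pytest.fixture(scope="session")
def stoplist():
    return corpus_prep.load_stopwords()


@pytest.fixture(scope="session")
def toy_hierarchy():
    """Neoplasms root with one child and grandchild, plus a kinase root."""
    return corpus_prep.MeshHierarchy(
        {
            "D009369": {"label": "Neoplasms", "synonyms": ["Tumors"], "parents": []},
            "D008175": {"label": "Lung Neoplasms", "synonyms": ["lung cancer"], "parents": ["D009369"]},
            "D002289": {
                "label": "Carcinoma, Non-Small-Cell Lung",
                "synonyms": ["NSCLC"],
                "parents": ["D008175"],
            },
            "D011494": {"label": "Protein Kinases", "synonyms": [], "parents": []},
            "D051096": {"label": "Unrelated Branch", "synonyms": [], "parents": []},
        }
    )


@pytest.fixture(scope="session")
def small_synth_config():
    """Scaled-down generator settings for fast structural tests."""
    return synth.SynthConfig(
        n_pk=6,
        n_cancer=5,
        n_true_pairs=8,
        docs_per_true_pair=10,
        background_docs=120,
        vocab_size=60,
        context_words_per_pair=4,
        doc_length=14,
        pki_count=12,
        trials_per_true_pair=2,
        cap_exceeders=1,
        year_range=(2005, 2015),
        active_fraction=1.0,
        relation_words=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def default_e2e_result(tmp_path_factory):
    """The full pipeline run on the default synthetic study (computed once)."""
    from kce import pipeline

    cfg = synth.SynthConfig()
    out = tmp_path_factory.mktemp("synth_default")
    paths = synth.end_to_end_fixture(cfg, out)
    split_cfg = splits.SplitConfig(
        target_year=2010,
        test_window=(2011, 2020),
        test_phase_filter="phase_iv_only",
        seed=cfg.seed,
    )
    result = pipeline.run_pipeline(
        paths,
        synth.pk_token_map(cfg),
        synth.cancer_token_map(cfg),
        split_cfg,
        seed=cfg.seed,
    )
    return cfg, result
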