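"""The synthetic song-culture generator and its ground truth."""

import pytest

from whalesong import (
    CultureConfig,
    compress_to_song_string,
    dsi,
    make_song_type,
    simulate_culture,
    theme_set,
    upgma,
    cut_tree,
    song_lsi_matrix,
    write_transcripts,
)


def test_same_seed_gives_byte_identical_output(tmp_path):
    cfg = CultureConfig(seed=42, noise=0.05, hybrid_probability=0.5)
    cat1, truth1 = simulate_culture(cfg)
    cat2, truth2 = simulate_culture(cfg)
    f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_transcripts(cat1, f1)
    write_transcripts(cat2, f2)
    assert f1.read_bytes() == f2.read_bytes()
    assert truth1.equals(truth2)


def test_zero_noise_one_population_song_strings_identical():
    cfg = CultureConfig(populations=("P",), years=(2016, 2016), seed=3,
                        noise=0.0, unit_edit_rate=0.0, hybrid_probability=0.0,
                        singers_per_population_per_year=5)
    cat, _ = simulate_culture(cfg)
    strings = {compress_to_song_string(s) for s in cat}
    assert len(strings) == 1


def test_zero_noise_same_type_full_similarity_cross_type_zero():
    cfg = CultureConfig(seed=7, noise=0.0, unit_edit_rate=0.0, hybrid_probability=0.0,
                        years=(2016, 2016), revolution_schedule=())
    cat, truth = simulate_culture(cfg)
    by_type = truth.set_index("singer_id")["true_song_types"].to_dict()
    m = song_lsi_matrix(cat)
    for i, a in enumerate(m.labels):
        for j, b in enumerate(m.labels):
            if i == j:
                continue
            if by_type[a] == by_type[b]:
                assert m.values[i, j] == 1.0
            else:
                assert m.values[i, j] == 0.0
    # same holds for repertoire overlap
    singers = {s.singer_id: s for s in cat}
    a, b = m.labels[0], m.labels[-1]
    assert dsi(theme_set(singers[a]), theme_set(singers[b])) == 0.0


def test_revolution_lag_recovery():
    """The receiving population's singers first cluster with the source in
    the configured arrival year (zero-noise case)."""
    t1 = make_song_type("T1", 6, seed=1, start_number=1)
    t2 = make_song_type("T2", 6, seed=2, start_number=11)
    cfg = CultureConfig(
        populations=("A", "B"), years=(2016, 2018), seed=5,
        song_types=(t1, t2), initial_types=(("A", "T1"), ("B", "T2")),
        revolution_schedule=(("T1", "B", 2017),),
        noise=0.0, unit_edit_rate=0.0, hybrid_probability=0.0,
    )
    cat, truth = simulate_culture(cfg)
    by_singer = truth.set_index("singer_id")
    m = song_lsi_matrix(cat)
    parts = cut_tree(upgma(m.to_dissimilarity()), 2)
    a_cluster = {parts[s] for s in m.labels if s.startswith("A")}
    assert len(a_cluster) == 1
    first_year_joined = min(
        int(by_singer.loc[s, "year"]) for s in m.labels
        if s.startswith("B") and parts[s] in a_cluster
    )
    assert first_year_joined == 2017
    # pre-arrival B singers stay apart
    assert all(parts[s] not in a_cluster
               for s in m.labels if s.startswith("B2016"))


def test_hybrid_singers_mix_both_repertoires():
    cfg = CultureConfig(seed=9, noise=0.0, unit_edit_rate=0.0, hybrid_probability=1.0)
    cat, truth = simulate_culture(cfg)
    hybrids = truth[truth["is_hybrid"]]
    assert len(hybrids) > 0
    singers = {s.singer_id: s for s in cat}
    resolved = cfg.resolved()
    repertoire = {t.id: set(t.theme_order()) for t in resolved.song_types}
    for _, row in hybrids.iterrows():
        new_type, old_type = row["true_song_types"].split("+")
        themes = theme_set(singers[row["singer_id"]])
        assert themes & repertoire[new_type]
        assert themes & repertoire[old_type]


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        simulate_culture(CultureConfig(singers_per_population_per_year=0))
    with pytest.raises(ValueError):
        CultureConfig(noise=1.5)
    with pytest.raises(ValueError):
        CultureConfig(revolution_schedule=(("T1", "ZZ", 2017),))
    with pytest.raises(ValueError):
        CultureConfig(revolution_schedule=(("T1", "FP", 1999),))


def test_progressive_evolution_changes_canon_gradually():
    cfg = CultureConfig(populations=("P",), years=(2016, 2018), seed=21,
                        noise=0.0, unit_edit_rate=0.2, hybrid_probability=0.0,
                        revolution_schedule=())
    cat, _ = simulate_culture(cfg)
    by_year = {}
    for s in cat:
        by_year.setdefault(s.year, s)
    # same theme's canonical phrase drifts across years but stays recognisable
    p16 = {str(p.theme): p.units for p in by_year[2016].phrases}
    p18 = {str(p.theme): p.units for p in by_year[2018].phrases}
    assert p16.keys() == p18.keys()
    assert any(p16[t] != p18[t] for t in p16)
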