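import numpy as np
import pytest

from dscahla import tasks
from dscahla.io import ALPHABET, HLAAllele, PairExample, PeptideRecord
from dscahla.model import PresentationModel
from dscahla.tasks import PositionFrequencyMatrix

from conftest import small_model_config


@pytest.fixture(scope="module")
def untrained_model(tiny_world):
    return PresentationModel(small_model_config(seed=9))


def test_predicted_core_is_always_nine_residues(tiny_world, untrained_model):
    world, pairs = tiny_world
    for scorer in ("window", "attention", "feature-norm"):
        pred = tasks.predict_core(untrained_model, "ACDEFGHIKLMNPQ",
                                  world.alleles[0].name, world.registry,
                                  scorer=scorer)
        assert len(pred.core) == 9
        assert pred.core == "ACDEFGHIKLMNPQ"[pred.start:pred.start + 9]
        assert len(pred.position_scores) == 14 - 9 + 1


def test_core_tie_breaks_leftmost(tiny_world, untrained_model):
    """A homopolymer peptide gives identical window scores; the leftmost wins."""
    world, _ = tiny_world
    pred = tasks.predict_core(untrained_model, "A" * 14,
                              world.alleles[0].name, world.registry,
                              scorer="window")
    assert pred.start == 0


def test_core_requires_nine_residues(tiny_world, untrained_model):
    world, _ = tiny_world
    with pytest.raises(ValueError):
        tasks.predict_core(untrained_model, "ACDEFGHI",
                           world.alleles[0].name, world.registry)


def test_core_prediction_deterministic(tiny_world, untrained_model):
    world, pairs = tiny_world
    pos = [p for p in pairs if p.label == 1][:10]
    _, a = tasks.predict_cores(untrained_model, pos, world.registry)
    _, b = tasks.predict_cores(untrained_model, pos, world.registry)
    assert [c.start for c in a] == [c.start for c in b]


def test_enumerate_windows_counts():
    assert len(tasks.enumerate_windows("A" * 25)) == 84
    assert len(tasks.enumerate_windows("A" * 12)) == 1
    for off, seq in tasks.enumerate_windows("ACDEFGHIKLMNPQRSTVWYACDEF"):
        assert "ACDEFGHIKLMNPQRSTVWYACDEF"[off:off + len(seq)] == seq


def test_enumerate_windows_closed_form():
    for length in range(1, 201):
        expected = sum(max(0, length - w + 1) for w in range(12, 20))
        assert len(tasks.enumerate_windows("A" * length)) == expected


def test_enumerate_windows_validates_bounds():
    with pytest.raises(ValueError):
        tasks.enumerate_windows("A" * 30, min_len=5, max_len=4)


def test_pfm_row_sums_and_information_content():
    counts = np.zeros((9, 21), dtype=int)
    counts[:, 0] = 7  # all cores identical
    pfm = PositionFrequencyMatrix(counts=counts, n_sequences=7)
    assert np.allclose(pfm.information_content(), np.log2(20))
    with pytest.raises(ValueError):
        PositionFrequencyMatrix(counts=counts, n_sequences=8)


def test_build_logo_conservation(tiny_world, untrained_model):
    world, pairs = tiny_world
    peps = [p.peptide for p in pairs if p.label == 1][:15]
    pfm = tasks.build_logo(untrained_model, peps, world.alleles[0].name,
                           world.registry, top_fraction=1.0)
    assert (pfm.counts.sum(axis=1) == 15).all()
    grouped = tasks.build_logo(untrained_model, peps, world.alleles[0].name,
                               world.registry, top_fraction=1.0,
                               group_by_start=True)
    assert sum(p.n_sequences for p in grouped.values()) == 15


def test_build_logo_empty_selection(tiny_world, untrained_model):
    world, pairs = tiny_world
    peps = [p.peptide for p in pairs if p.label == 1][:5]
    with pytest.raises(ValueError, match="selects no peptide"):
        tasks.build_logo(untrained_model, peps, world.alleles[0].name,
                         world.registry, top_fraction=0.01)


@pytest.fixture(scope="module")
def panel_setup(tiny_world):
    """A registry whose allele names are the printed DRB1 panel."""
    world, _ = tiny_world
    chains = [(a.alpha_chain, a.beta_chain) for a in world.alleles]
    registry = {
        name: HLAAllele(name, *chains[i % len(chains)])
        for i, name in enumerate(tasks.DEFAULT_PANEL)
    }
    model = PresentationModel(small_model_config(seed=10))
    return model, registry


def test_default_panel_is_the_eight_drb1_alleles():
    assert len(tasks.DEFAULT_PANEL) == 8
    for code in ("01:01", "03:01", "04:01", "07:01", "08:01", "11:01",
                 "13:01", "15:01"):
        assert any(f"DRB1*{code}" in name for name in tasks.DEFAULT_PANEL)


def test_prevalence_filter_is_strictly_greater(panel_setup):
    model, registry = panel_setup
    antibody = "ACDEFGHIKLMNPQRSTVWYACD"
    base = tasks.immunogenicity_screen(model, antibody, registry, {},
                                       cutoff=0.0)
    # find the cores the screen retains, then prevalence-filter them
    assert base.total_unique_cores > 0
    _, cores = tasks.predict_cores(
        model,
        [PairExample(PeptideRecord("w", seq), tasks.DEFAULT_PANEL[0], 0)
         for _, seq in tasks.enumerate_windows(antibody)],
        registry)
    target = cores[0].core
    for prevalence, retained in ((21, True), (22, True), (23, False)):
        rep = tasks.immunogenicity_screen(model, antibody, registry,
                                          {target: prevalence}, cutoff=0.0)
        counts_with = rep.per_allele_core_counts[tasks.DEFAULT_PANEL[0]]
        base_count = base.per_allele_core_counts[tasks.DEFAULT_PANEL[0]]
        if retained:
            assert counts_with == base_count
        else:
            assert counts_with == base_count - 1


def test_cutoff_one_removes_everything(panel_setup):
    model, registry = panel_setup
    rep = tasks.immunogenicity_screen(model, "ACDEFGHIKLMNPQRSTVWY", registry,
                                      {}, cutoff=1.0)
    assert all(v == 0 for v in rep.per_allele_core_counts.values())


def test_counts_monotone_in_cutoff(panel_setup):
    model, registry = panel_setup
    antibody = "ACDEFGHIKLMNPQRSTVWYACDEFGH"
    totals = [tasks.immunogenicity_screen(model, antibody, registry, {},
                                          cutoff=c).total_unique_cores
              for c in (0.0, 0.4, 0.8, 1.0)]
    assert totals == sorted(totals, reverse=True)


def test_short_antibody_warns_and_returns_zero(panel_setup):
    model, registry = panel_setup
    with pytest.warns(UserWarning):
        rep = tasks.immunogenicity_screen(model, "ACDEFGH", registry, {})
    assert rep.total_unique_cores == 0


def test_missing_panel_allele_errors(panel_setup, tiny_world):
    model, _ = panel_setup
    world, _ = tiny_world
    with pytest.raises(KeyError):
        tasks.immunogenicity_screen(model, "ACDEFGHIKLMNPQRSTVWY",
                                    world.registry, {})


def test_malformed_prevalence_table(panel_setup):
    model, registry = panel_setup
    with pytest.raises(ValueError):
        tasks.immunogenicity_screen(model, "ACDEFGHIKLMNPQRSTVWY", registry,
                                    {"SHORT": 5})
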