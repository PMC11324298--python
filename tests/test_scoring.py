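"""Surrogate scorer: penalty formula, delta-score, backend registry."""

import numpy as np
import pytest

from adductscan.binder import PSSM
from adductscan.chem import Peptide, apply_adduct, default_registry
from adductscan.mhc import AlleleModel, ComplexModel
from adductscan.scoring import (
    ScoreReport,
    SurrogateParams,
    adduct_penalty,
    delta_score,
    register_backend,
    registered_backends,
    score_complex,
    write_score_report_tsv,
)
from adductscan.synthetic import PlantSpec, gen_allele, gen_pssm


def make_allele(exposure, anchors=frozenset({5, 9})):
    length = len(exposure)
    return AlleleModel("TEST", frozenset({length}),
                       {length: anchors}, {length: tuple(exposure)})


def bare_model(seq, mods=None):
    return ComplexModel(Peptide(seq, modifications=mods or {}), None,
                        np.empty((0, 4)), "none")


@pytest.fixture
def allele():
    return make_allele([0.5, 0.5, 0.5, 1.0, 0.1, 1.0, 1.0, 0.0, 0.1])


def test_unmodified_peptide_has_zero_penalties(allele):
    rep = score_complex(bare_model("LAGKNLTHI"), allele)
    assert not rep.adducted
    assert rep.total == 0.0  # no PSSM term, no penalties
    np.testing.assert_array_equal(rep.per_position, np.zeros(9))


def test_penalty_formula_limits(allele, registry):
    sp = registry.get("pyrrole")
    params = SurrogateParams(penalty_scale=10.0)
    # fully exposed position costs nothing; fully buried costs kappa*bulk
    assert adduct_penalty(4, sp, allele, params, length=9) == 0.0
    assert adduct_penalty(8, sp, allele, params, length=9) == 10.0
    assert adduct_penalty(1, sp, allele, params, length=9) == pytest.approx(5.0)


def test_clash_term_counts_receptor_atoms_in_radius(registry):
    allele = make_allele([1.0] * 9)
    backbone = np.zeros((9, 3))
    backbone[:, 0] = np.arange(9)
    # two pseudo-atoms within 2.5 A of position 4's CA at (3,0,0), one outside
    receptor = np.array([[3.0, 1.0, 0.0, 2.0],
                         [4.0, 2.0, 0.0, 2.0],
                         [3.0, 9.0, 0.0, 2.0]])
    model = ComplexModel(Peptide("LAGKNLTHI"), backbone, receptor, "t")
    params = SurrogateParams(clash_term_enabled=True, clash_weight=1.0,
                             clash_radius=2.5)
    pen = adduct_penalty(4, registry.get("pyrrole"), allele, params,
                         model=model)
    # exposure term 0 (exposure 1.0); brute-force distance check gives 2
    dists = np.linalg.norm(receptor[:, :3] - backbone[3], axis=1)
    assert int((dists <= 2.5).sum()) == 2
    assert pen == 2.0


def test_delta_score_equals_penalty(allele, registry, rng):
    params = SurrogateParams(penalty_scale=7.0)
    for _ in range(50):
        exposure = rng.uniform(0, 1, size=9)
        a = make_allele(exposure)
        pos = int(rng.integers(1, 10))
        seq = list(rng.choice(list("ACDEFGHILMNPQRSTVWY"), size=9))
        seq[pos - 1] = "K"
        model = bare_model("".join(seq))
        d = delta_score(model, pos, "pyrrole", a, params=params)
        expected = adduct_penalty(pos, registry.get("pyrrole"), a, params,
                                  length=9)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d >= 0.0


def test_delta_score_monotone_in_exposure(registry):
    deltas = []
    for e in np.linspace(0, 1, 11):
        a = make_allele([0.5, 0.5, 0.5, e, 0.1, 0.5, 0.5, 0.5, 0.1])
        d = delta_score(bare_model("LAGKNLTHI"), 4, "pyrrole", a)
        deltas.append(d)
    assert all(x >= y - 1e-12 for x, y in zip(deltas, deltas[1:]))
    assert deltas[-1] == 0.0  # fully exposed accommodates the adduct freely


def test_delta_score_rejects_non_lysine(allele):
    with pytest.raises(ValueError, match="lysine"):
        delta_score(bare_model("LAGKNLTHI"), 5, "pyrrole", allele)


def test_score_includes_pssm_term_and_sums_to_total(allele):
    spec = PlantSpec(seed=5)
    pssm = gen_pssm(spec)
    a = gen_allele(spec)
    model = bare_model(pssm.consensus().replace("K", "A"))
    rep = score_complex(model, a, pssm=pssm)
    manual = -sum(pssm.entry(i, aa)
                  for i, aa in enumerate(model.peptide.sequence, start=1))
    assert rep.total == pytest.approx(manual, abs=1e-9)
    assert rep.total == pytest.approx(rep.per_position.sum(), abs=1e-9)


def test_scoring_is_pure_and_deterministic(allele):
    model = bare_model("LAGKNLTHI", mods={4: "pyrrole"})
    r1 = score_complex(model, allele)
    r2 = score_complex(model, allele, n_models=250, top_k=5)  # documented no-op
    assert r1.total == r2.total
    np.testing.assert_array_equal(r1.per_position, r2.per_position)
    assert model.peptide.modifications == {4: "pyrrole"}  # input unmutated


def test_unsupported_length_and_unknown_backend(allele):
    with pytest.raises(ValueError, match="length"):
        score_complex(bare_model("AAAA"), allele)
    with pytest.raises(ValueError, match="registered"):
        score_complex(bare_model("LAGKNLTHI"), allele, backend="allatom")


def test_backend_registry_duplicate_and_custom(allele):
    def noop(model, a, pssm, params, registry):
        return ScoreReport(0.0, np.zeros(len(model.peptide)), "noop", False)

    if "noop_test" not in registered_backends():
        register_backend("noop_test", noop)
    rep = score_complex(bare_model("LAGKNLTHI"), allele, backend="noop_test")
    assert rep.total == 0.0
    with pytest.raises(ValueError, match="already registered"):
        register_backend("surrogate", noop)


def test_allele_contrast_restrictive_scores_worse(rng):
    """Lower non-anchor exposure (restrictive groove) means larger mean
    delta-score over any peptide set."""
    base = rng.uniform(0.5, 1.0, size=9)
    permissive = make_allele(base)
    restrictive = make_allele(np.clip(base - 0.3, 0.05, 1.0))
    deltas_p, deltas_r = [], []
    for _ in range(20):
        pos = int(rng.choice([1, 2, 3, 4, 6, 7, 8]))
        seq = list(rng.choice(list("ACDEFGHILMNPQRSTVWY"), size=9))
        seq[pos - 1] = "K"
        model = bare_model("".join(seq))
        deltas_p.append(delta_score(model, pos, "pyrrole", permissive))
        deltas_r.append(delta_score(model, pos, "pyrrole", restrictive))
    assert np.mean(deltas_r) > np.mean(deltas_p)


def test_score_report_tsv(tmp_path, allele):
    rep = score_complex(bare_model("LAGKNLTHI", mods={4: "pyrrole"}), allele)
    path = tmp_path / "report.tsv"
    write_score_report_tsv(rep, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "position\tscore"
    assert len(lines) == 11  # header + 9 positions + total
    assert lines[-1].startswith("total\t")
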