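"""HMM likelihood, posterior-emission and decoding correctness."""

import numpy as np
import pytest
from scipy.stats import norm

from fragmeth.errors import NumericalError, UsageError
from fragmeth.features import CpGObservation, Fragment
from fragmeth.hmm import (
    DistanceBins, FragmentMethylationHMM, MethylationPrior, posterior_emission,
    viterbi_decode,
)

from .conftest import random_model
from .oracles import brute_force_loglik, brute_force_viterbi, emission_prob


def make_fragment(z_rows, offset=10, distances=None, positions=None, chrom="chr1"):
    z_rows = np.atleast_2d(np.asarray(z_rows, dtype=float))
    n = len(z_rows)
    distances = distances if distances is not None else [25] * (n - 1)
    if positions is None:
        positions = [offset + int(sum(distances[:t]))
                     for t in range(n)]
    frag = Fragment(chrom, 0, 400, name="t")
    for t in range(n):
        frag.observations.append(
            CpGObservation(
                ref_position=positions[t], offset=positions[t],
                distance_to_prev=None if t == 0 else int(distances[t - 1]),
                fragment_length=0, normalized_coverage=0, distance_to_center=0,
                z=z_rows[t],
            )
        )
    return frag


class TestDistanceBins:
    def test_bin_edges_are_half_open(self):
        bins = DistanceBins((10, 20, 50, 100, 200, 500), (25, 50, 75, 100, 150))
        assert bins.distance_bin(1) == 0
        assert bins.distance_bin(10) == 0
        assert bins.distance_bin(11) == 1
        assert bins.distance_bin(500) == 5
        assert bins.distance_bin(501) == 6
        assert bins.offset_bin(0) == 0
        assert bins.offset_bin(151) == 5
        assert bins.n_distance_bins == 7 and bins.n_offset_bins == 6

    def test_edges_must_increase(self):
        with pytest.raises(UsageError):
            DistanceBins((10, 10), (25,))


class TestPosteriorEmission:
    def test_uniform_prior_reduces_to_normalized_likelihood(self):
        lu, lm = np.log(0.2), np.log(0.6)
        pu, pm = posterior_emission(lu, lm, k=0.5)
        assert pm == pytest.approx(0.6 / 0.8)
        assert pu + pm == pytest.approx(1.0)

    def test_degenerate_prior_forces_state(self):
        assert posterior_emission(np.log(0.5), np.log(1e-30), k=1.0)[1] == 1.0
        assert posterior_emission(np.log(1e-30), np.log(0.5), k=0.0)[0] == 1.0

    def test_worked_example(self):
        # L_m=0.3, L_u=0.1, k'=0.25 -> 0.3*0.25/(0.3*0.25+0.1*0.75) = 0.5
        pu, pm = posterior_emission(np.log(0.1), np.log(0.3), k=0.25)
        assert pm == pytest.approx(0.5, abs=1e-12)

    def test_prior_weight_shrinks_toward_half(self):
        # w=0 makes any k behave as 0.5
        lu, lm = np.log(0.2), np.log(0.6)
        assert posterior_emission(lu, lm, k=0.99, w=0.0)[1] == pytest.approx(0.75)

    def test_underflow_is_resolved_in_log_space(self):
        pu, pm = posterior_emission(-5000.0, -5001.0, k=0.5)
        assert pu + pm == pytest.approx(1.0)
        assert 0 < pm < 1

    def test_invalid_k_rejected(self):
        with pytest.raises(UsageError):
            posterior_emission(0.0, 0.0, k=1.5)


class TestEmissionLoglik:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        model = random_model(rng)
        obs = make_fragment(rng.normal(size=(1, 3))).observations[0]
        for s in (0, 1):
            direct = np.log(
                emission_prob(obs.z, s, model.emission_weights_,
                              model.emission_means_, model.emission_vars_)
            )
            assert model.emission_loglik(obs, s) == pytest.approx(direct, abs=1e-12)

    def test_collapsed_mixture_peaks_at_component_mean(self):
        model = FragmentMethylationHMM.from_parameters(
            np.tile([0.5, 0.5], (6, 1)), np.tile(np.eye(2) * 0.8 + 0.1, (7, 1, 1)),
            np.full((2, 3), 1e-6),  # weight ~0 -> component i only
            np.zeros((2, 3, 2)), np.ones((2, 3, 2)),
        )
        obs = make_fragment([[0.0, 0.0, 0.0]]).observations[0]
        peak = 3 * norm.logpdf(0.0, 0.0, 1.0)
        assert model.emission_loglik(obs, 0) == pytest.approx(peak, abs=1e-4)

    def test_nonfinite_feature_rejected(self):
        model = random_model(np.random.default_rng(1))
        obs = make_fragment([[np.nan, 0, 0]]).observations[0]
        with pytest.raises(NumericalError):
            model.emission_loglik(obs, 0)


class TestForwardViterbi:
    @pytest.mark.parametrize("n_cpgs", [1, 2, 5, 8])
    def test_forward_matches_enumeration(self, n_cpgs):
        rng = np.random.default_rng(n_cpgs)
        model = random_model(rng)
        frag = make_fragment(
            rng.normal(size=(n_cpgs, 3)),
            distances=rng.integers(2, 700, size=max(0, n_cpgs - 1)).tolist(),
        )
        got = model.score_fragments([frag])[0]
        assert got == pytest.approx(brute_force_loglik(frag, model), rel=1e-10)

    def test_viterbi_matches_exhaustive_argmax_with_prior(self):
        rng = np.random.default_rng(42)
        model = random_model(rng)
        for _ in range(25):
            n = int(rng.integers(1, 9))
            frag = make_fragment(
                rng.normal(size=(n, 3)),
                distances=rng.integers(2, 700, size=max(0, n - 1)).tolist(),
            )
            ks = {o.ref_position: float(rng.uniform(0.05, 0.95))
                  for o in frag.observations}
            prior = MethylationPrior(k={("chr1", p): v for p, v in ks.items()})
            dec = model.decode_fragment(frag, prior)
            best, _ = brute_force_viterbi(frag, model, prior_k=ks)
            assert dec.path.tolist() == best.tolist()

    def test_single_cpg_path_is_pointwise_argmax(self):
        rng = np.random.default_rng(3)
        model = random_model(rng)
        frag = make_fragment(rng.normal(size=(1, 3)), offset=40)
        dec = model.decode_fragment(frag)
        b = model.bins_.offset_bin(40)
        lu = model.emission_loglik(frag.observations[0], 0)
        lm = model.emission_loglik(frag.observations[0], 1)
        pu, pm = posterior_emission(lu, lm, 0.5)
        scores = np.log(model.startprob_[b]) + np.log([pu, pm])
        assert dec.path[0] == int(np.argmax(scores))

    def test_uninformative_emissions_with_certain_prior_gives_all_m(self):
        # identical mixtures for both states: only the prior speaks
        shared = np.array([[[0.0, 0.5]] * 3] * 2)
        model = FragmentMethylationHMM.from_parameters(
            np.tile([0.5, 0.5], (6, 1)), np.tile(np.full((2, 2), 0.5), (7, 1, 1)),
            np.full((2, 3), 0.5), shared, np.ones((2, 3, 2)),
        )
        frag = make_fragment(np.zeros((4, 3)))
        prior = MethylationPrior(k={}, default_k=1.0)
        dec = model.decode_fragment(frag, prior)
        assert dec.path.tolist() == [1, 1, 1, 1]
        assert np.allclose(dec.posterior_m, 1.0)

    def test_all_ties_resolve_toward_m_deterministically(self):
        shared = np.array([[[0.0, 0.5]] * 3] * 2)
        model = FragmentMethylationHMM.from_parameters(
            np.tile([0.5, 0.5], (6, 1)), np.tile(np.full((2, 2), 0.5), (7, 1, 1)),
            np.full((2, 3), 0.5), shared, np.ones((2, 3, 2)),
        )
        frag = make_fragment(np.zeros((5, 3)))
        d1 = model.decode_fragment(frag)
        d2 = model.decode_fragment(frag)
        assert d1.path.tolist() == [1] * 5 == d2.path.tolist()

    def test_label_swap_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(9)
        model = random_model(rng)
        swapped = FragmentMethylationHMM.from_parameters(
            model.startprob_[:, ::-1],
            model.transmat_[:, ::-1, ::-1],
            model.emission_weights_[::-1],
            model.emission_means_[::-1],
            model.emission_vars_[::-1],
        )
        frags = [
            make_fragment(rng.normal(size=(int(rng.integers(1, 8)), 3)))
            for _ in range(10)
        ]
        for f in frags:
            assert model.score_fragments([f])[0] == pytest.approx(
                swapped.score_fragments([f])[0], rel=1e-12
            )

    def test_prior_weight_zero_ignores_prior_contents(self):
        rng = np.random.default_rng(5)
        model = random_model(rng)
        frag = make_fragment(rng.normal(size=(6, 3)))
        p1 = MethylationPrior(k={("chr1", o.ref_position): 0.99 for o in frag.observations},
                              weight=0.0)
        p2 = MethylationPrior(k={("chr1", o.ref_position): 0.01 for o in frag.observations},
                              weight=0.0)
        d1, d2 = model.decode_fragment(frag, p1), model.decode_fragment(frag, p2)
        assert d1.path.tolist() == d2.path.tolist()
        assert np.allclose(d1.posterior_m, d2.posterior_m)

    def test_posteriors_are_probabilities(self):
        rng = np.random.default_rng(6)
        model = random_model(rng)
        frag = make_fragment(rng.normal(size=(7, 3)))
        dec = viterbi_decode(frag, model)
        assert ((dec.posterior_m >= 0) & (dec.posterior_m <= 1)).all()
        assert len(dec.path) == 7

    def test_empty_fragment_rejected(self):
        model = random_model(np.random.default_rng(7))
        with pytest.raises(UsageError):
            model.decode_fragment(Fragment("chr1", 0, 100))


class TestSerialization:
    def test_round_trip_preserves_decoding(self, tmp_path):
        rng = np.random.default_rng(17)
        model = random_model(rng)
        path = tmp_path / "model.json"
        model.to_json(str(path))
        loaded = FragmentMethylationHMM.from_json(str(path))
        frag = make_fragment(rng.normal(size=(6, 3)))
        d1, d2 = model.decode_fragment(frag), loaded.decode_fragment(frag)
        assert d1.path.tolist() == d2.path.tolist()
        assert np.allclose(d1.posterior_m, d2.posterior_m)
        assert d1.loglik == pytest.approx(d2.loglik, rel=1e-12)

    def test_version_mismatch_rejected(self, tmp_path):
        import json

        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"format_version": 99}))
        with pytest.raises(UsageError):
            FragmentMethylationHMM.from_json(str(path))


class TestPrior:
    def test_bedgraph_round_trip_and_default(self, tmp_path):
        bg = tmp_path / "p.bedgraph"
        bg.write_text("chr1\t10\t12\t0.8\nchr1\t50\t52\t0.2\n")
        prior = MethylationPrior.from_bedgraph(str(bg))
        assert prior.get("chr1", 10) == 0.8
        assert prior.get("chr1", 999) == pytest.approx(0.5)  # track mean
        assert prior.effective("chr1", 10) == 0.8
        prior.weight = 0.5
        assert prior.effective("chr1", 10) == pytest.approx(0.65)

    def test_invalid_weight(self):
        with pytest.raises(UsageError):
            MethylationPrior(weight=1.5)
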