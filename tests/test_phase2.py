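"""Dataset-wide clustering of bin summaries and label propagation."""

import numpy as np
import pytest

from clickchain import phase2
from clickchain.phase1 import BinClusterSummary
from clickchain.phase2 import Phase2Params, assign_labels, bin_similarity, cluster_summaries

from conftest import gaussian_spectra


def make_summary(spec, env=None, idi=None, bin_index=0, member_ids=None, cluster_id=0):
    spec = np.asarray(spec, dtype=float)
    env = np.asarray(env if env is not None else np.linspace(1, 0, 16))
    idi = np.asarray(idi if idi is not None else np.r_[1.0, np.zeros(9)])
    member_ids = np.asarray(member_ids if member_ids is not None else [0])
    return BinClusterSummary(
        bin_index=bin_index,
        bin_start_s=bin_index * 300.0,
        cluster_id=cluster_id,
        mean_spectrum=(spec - spec.min()) / (spec.max() - spec.min()),
        mean_envelope=env,
        idi_hist=idi,
        n_members=len(member_ids),
        member_ids=member_ids,
    )


def class_summaries(n, center, rng, start_bin=0, ids_from=0):
    specs = gaussian_spectra(n, center, rng=rng, noise=1.0)
    out = []
    for k in range(n):
        env = np.exp(-((np.arange(16) - 8) ** 2) / (2 * (2 + center / 20) ** 2))
        env += rng.normal(0, 0.02, 16)
        out.append(
            make_summary(
                specs[k], env=env, bin_index=start_bin + k,
                member_ids=np.arange(ids_from + 100 * k, ids_from + 100 * k + 60),
            )
        )
    return out


class TestBinSimilarity:
    def test_self_similarity_is_one(self, rng):
        s = make_summary(gaussian_spectra(1, 10, rng=rng)[0])
        assert bin_similarity(s, s) == pytest.approx(1.0)

    def test_mean_of_components(self, rng):
        spec = gaussian_spectra(1, 10, rng=rng)[0]
        # identical spectra; envelopes orthogonal in correlation (r = 0)
        e1 = np.array([1.0, 0.0, 1.0, 0.0] * 4)
        e2 = np.array([1.0, 1.0, 0.0, 0.0] * 4)
        a = make_summary(spec, env=e1)
        b = make_summary(spec, env=e2)
        assert bin_similarity(a, b) == pytest.approx(0.5, abs=1e-10)

    def test_matches_componentwise_oracle(self, rng):
        a = make_summary(gaussian_spectra(1, 10, rng=rng)[0], env=rng.normal(size=16))
        b = make_summary(gaussian_spectra(1, 20, rng=rng)[0], env=rng.normal(size=16))
        def clipped_r(x, y):
            r = np.corrcoef(x, y)[0, 1]
            return min(max(r, 0.0), 1.0)
        expected = 0.5 * (
            clipped_r(a.mean_spectrum, b.mean_spectrum) + clipped_r(a.mean_envelope, b.mean_envelope)
        )
        assert bin_similarity(a, b) == pytest.approx(expected, abs=1e-10)


class TestClusterSummaries:
    def test_four_planted_classes_recovered(self, rng):
        summaries = []
        truth = []
        for i, center in enumerate((5, 13, 21, 29)):
            summaries += class_summaries(12, center, rng, start_bin=40 * i, ids_from=10_000 * i)
            truth += [i] * 12
        truth = np.array(truth)
        params = Phase2Params(min_phase2_size=5, seed=0)
        _, templates, _ = cluster_summaries(summaries, params)
        majority = {}
        for t in templates:
            classes, counts = np.unique(truth[t.member_summary_idx], return_counts=True)
            maj = classes[np.argmax(counts)]
            majority.setdefault(maj, []).append(counts.max() / counts.sum())
        assert set(majority) == {0, 1, 2, 3}
        assert all(p >= 0.9 for ps in majority.values() for p in ps)

    def test_identical_summaries_form_single_template(self, rng):
        spec = gaussian_spectra(1, 10, rng=rng)[0]
        summaries = [make_summary(spec, bin_index=i, member_ids=[i]) for i in range(60)]
        _, templates, _ = cluster_summaries(summaries, Phase2Params(min_phase2_size=5, seed=0))
        assert len(templates) == 1
        # tie-broken label propagation on an all-identical graph keeps the
        # bulk of the members in one cluster (10% weak-node prune on top)
        assert templates[0].n_members >= 36

    def test_too_few_summaries_yield_no_templates(self, rng, caplog):
        summaries = class_summaries(30, 10, rng)
        with caplog.at_level("WARNING", logger="clickchain.phase2"):
            _, templates, _ = cluster_summaries(summaries, Phase2Params(min_phase2_size=50))
        assert templates == []
        assert "no phase-2 cluster" in caplog.text

    def test_deterministic_given_seed(self, rng):
        summaries = class_summaries(12, 10, rng) + class_summaries(12, 25, rng, ids_from=90_000)
        p = Phase2Params(min_phase2_size=5, seed=11)
        part1, _, _ = cluster_summaries(summaries, p)
        part2, _, _ = cluster_summaries(summaries, p)
        np.testing.assert_array_equal(part1.labels, part2.labels)


class TestAssignLabels:
    def make_templates(self, rng):
        summaries = class_summaries(6, 8, rng) + class_summaries(6, 25, rng, ids_from=50_000)
        _, templates, _ = cluster_summaries(summaries, Phase2Params(min_phase2_size=3, seed=0))
        return summaries, templates

    def test_two_templates_merged_under_one_name(self, rng):
        summaries, templates = self.make_templates(rng)
        assert len(templates) >= 2
        label_map = {t.class_id: "A" for t in templates}
        labeled, prop = assign_labels(templates, summaries, label_map)
        assert set(prop["label"]) == {"A"}

    def test_unmapped_template_kept_as_unlabeled(self, rng):
        summaries, templates = self.make_templates(rng)
        labeled, prop = assign_labels(templates, summaries, {templates[0].class_id: "A"})
        assert phase2.UNLABELED in set(t.label for t in labeled)
        assert set(prop["label"]) >= {"A", phase2.UNLABELED}

    def test_propagation_count_identity(self, rng):
        summaries, templates = self.make_templates(rng)
        _, prop = assign_labels(templates, summaries, {})
        expected = sum(
            summaries[i].n_members for t in templates for i in t.member_summary_idx
        )
        assert len(prop) == expected
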