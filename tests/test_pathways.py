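"""Pathway tracing, Gestalt string distances, Ward clustering, contacts."""

import difflib

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from wepath import pathways as pw, surrogate as sg
from wepath.pathways import ClusterTree, Pathway

ALPHABET = "TOPXS"


def random_pairs(n, rng, min_len=1, max_len=30):
    for _ in range(n):
        s1 = "".join(rng.choice(list(ALPHABET), rng.integers(min_len, max_len + 1)))
        s2 = "".join(rng.choice(list(ALPHABET), rng.integers(min_len, max_len + 1)))
        yield s1, s2


def oracle_matched(a: str, b: str) -> int:
    """Independent brute-force Ratcliff--Obershelp matched-character count:
    scans every (i, j) start pair for the longest common substring (earliest
    in a, then b, on ties), then recurses on the flanks."""
    if not a or not b:
        return 0
    besti = bestj = best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k > best:
                besti, bestj, best = i, j, k
    if best == 0:
        return 0
    return (best + oracle_matched(a[:besti], b[:bestj])
            + oracle_matched(a[besti + best:], b[bestj + best:]))


class TestGestaltSimilarity:
    def test_identical_strings(self):
        assert pw.gestalt_similarity("TOPT", "TOPT") == 1.0

    def test_disjoint_alphabets(self):
        assert pw.gestalt_similarity("TTT", "OOO") == 0.0

    def test_worked_pair(self):
        # "OPT" is a substring of "OOPT": M = 3, 2*3/(4+3) = 6/7
        assert pw.gestalt_similarity("OOPT", "OPT") == pytest.approx(6 / 7)

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            pw.gestalt_similarity("", "TOP")

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for s1, s2 in random_pairs(150, rng):
            expected = 2 * oracle_matched(s1, s2) / (len(s1) + len(s2))
            assert pw.gestalt_similarity(s1, s2) == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_agrees_with_difflib_ratio(self):
        rng = np.random.default_rng(21)
        for s1, s2 in random_pairs(150, rng):
            ref = difflib.SequenceMatcher(None, s1, s2, autojunk=False).ratio()
            assert pw.gestalt_similarity(s1, s2) == pytest.approx(ref,
                                                                  abs=1e-12)


class TestPathwayDistance:
    def test_equal_length_is_one_minus_similarity(self):
        s1, s2 = "TOPX", "TOXP"
        assert pw.pathway_distance(s1, s2) == pytest.approx(
            1.0 - pw.gestalt_similarity(s1, s2))

    def test_worked_pair_with_length_correction(self):
        # (1 - 6/7) / (3/4) = 4/21
        assert pw.pathway_distance("OOPT", "OPT") == pytest.approx(4 / 21)

    def test_symmetric_zero_diagonal_positive(self):
        rng = np.random.default_rng(5)
        for s1, s2 in random_pairs(100, rng):
            d12 = pw.pathway_distance(s1, s2)
            assert d12 == pytest.approx(pw.pathway_distance(s2, s1), abs=1e-14)
            assert d12 >= 0
            if s1 == s2:
                assert d12 == 0.0
            else:
                assert d12 > 0.0
        assert pw.pathway_distance("TOP", "TOP") == 0.0


class TestClustering:
    def test_two_items_merge_at_their_distance(self):
        dm = np.array([[0.0, 0.8], [0.8, 0.0]])
        tree = pw.cluster(dm)
        assert tree.heights[0] == pytest.approx(0.8)

    def test_two_tight_groups_merge_last_and_high(self):
        rng = np.random.default_rng(3)
        n = 8
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < 4) == (j < 4)
                dm[i, j] = dm[j, i] = rng.uniform(0.01, 0.05) if same else \
                    rng.uniform(5.0, 5.2)
        tree = pw.cluster(dm)
        assert tree.heights[-1] > 10 * tree.heights[-2]

    def test_matches_independent_ward_implementation(self):
        # Lance-Williams recursion oracle, O(n^3)
        rng = np.random.default_rng(8)
        x = rng.random((10, 3))
        dm = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))

        def ward_oracle(d0):
            n = d0.shape[0]
            d = d0.copy().astype(float)
            size = {i: 1 for i in range(n)}
            active = list(range(n))
            heights = []
            d = {(i, j): d0[i, j] for i in range(n) for j in range(i + 1, n)}
            nxt = n
            while len(active) > 1:
                (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
                heights.append(h)
                si, sj = size[i], size[j]
                newd = {}
                for k in active:
                    if k in (i, j):
                        continue
                    dik = d[tuple(sorted((i, k)))]
                    djk = d[tuple(sorted((j, k)))]
                    dij = h
                    sk = size[k]
                    tot = si + sj + sk
                    val = np.sqrt(((si + sk) * dik ** 2 + (sj + sk) * djk ** 2
                                   - sk * dij ** 2) / tot)
                    newd[(k, nxt)] = val
                active = [k for k in active if k not in (i, j)]
                d = {kv: v for kv, v in d.items()
                     if i not in kv and j not in kv}
                d.update(newd)
                size[nxt] = si + sj
                active.append(nxt)
                nxt += 1
            return np.array(heights)

        tree = pw.cluster(dm)
        np.testing.assert_allclose(tree.heights, ward_oracle(dm), atol=1e-8)


class TestCutTree:
    @staticmethod
    def tree_from_heights(heights):
        # chain merges: (0,1), (new,2), (new,3), ... with given heights
        n = len(heights) + 1
        Z = []
        cur = 0
        for k, h in enumerate(heights):
            a = cur if k else 0
            b = k + 1 if k else 1
            Z.append([a, b, h, k + 2])
            cur = n + k
        return ClusterTree(np.array(Z, dtype=float), n)

    def test_cut_in_largest_gap(self):
        tree = self.tree_from_heights([0.1, 0.12, 0.9])
        labels, n_classes, degenerate = pw.cut_tree(tree)
        assert n_classes == 2 and not degenerate

    def test_all_heights_equal_is_one_flagged_class(self):
        tree = self.tree_from_heights([0.3, 0.3, 0.3])
        labels, n_classes, degenerate = pw.cut_tree(tree)
        assert n_classes == 1 and degenerate
        assert np.all(labels == 1)

    def test_forced_class_count(self):
        tree = self.tree_from_heights([0.1, 0.12, 0.9])
        labels, n_classes, _ = pw.cut_tree(tree, n_classes=3)
        assert n_classes == 3

    @pytest.mark.parametrize("motifs,rate", [
        (["OOOOPPPP", "XXXXSSSS"], 0.05),
        (["OOOOPPPP", "XXXXSSSS", "TTTTTTTT"], 0.10),
    ])
    def test_planted_classes_recovered(self, motifs, rate):
        seqs, truth = sg.generate_label_sequences(motifs, 50, rate, 1, seed=2)
        tree = pw.cluster(pw.distance_matrix(seqs))
        labels, n_classes, _ = pw.cut_tree(tree)
        assert n_classes == len(motifs)
        assert adjusted_rand_score(truth, labels) >= 0.9


@pytest.fixture(scope="module")
def traced(h_record):
    return pw.trace_pathways(h_record)


class TestTracedPathways:
    def test_every_pathway_ends_in_the_product_state(self, traced):
        assert len(traced) > 0
        for p in traced:
            r_last = np.hypot(*p.frames[-1])
            assert r_last < sg.R_PRODUCT

    def test_weights_sum_to_total_recycled_weight(self, traced, h_record):
        total = h_record.recycled_weight_series().sum()
        assert sum(p.weight for p in traced) == pytest.approx(total, abs=1e-12)

    def test_discretized_labels_match_frames(self, traced, h_params):
        for p in traced[:20]:
            s = pw.discretize(p, h_params)
            assert len(s) == len(p.frames)
            assert s[-1] == "T"     # product entry is the central carbon
            assert set(s) <= {"T", "O", "P"}   # three-letter alphabet

    def test_contact_distribution_normalized(self, traced, h_params):
        dist = pw.contact_distribution(traced, h_params)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert set(dist) == set(h_params.label_alphabet)


class TestContactDistribution:
    def make_path(self, xy, weight=1.0):
        frames = np.tile(xy, (4, 1))
        return Pathway(frames=frames, frames_all=frames, weight=weight,
                       start_iteration=1, end_iteration=4)

    def test_single_site_pathway_concentrates_probability(self, h_params):
        p = self.make_path(h_params.site_xy[0])  # parked at the first O site
        dist = pw.contact_distribution([p], h_params)
        assert dist["O"] == pytest.approx(1.0)

    def test_pathway_outside_contact_shell_rejected(self, h_params):
        p = self.make_path(np.array([20.0, 0.0]))
        with pytest.raises(ValueError, match="ion-pair"):
            pw.contact_distribution([p], h_params)

    def test_reweighting_then_renormalizing_is_invariant(self, h_params):
        a = self.make_path(h_params.site_xy[0], weight=0.2)
        b = self.make_path(h_params.site_xy[1], weight=0.6)
        d1 = pw.contact_distribution([a, b], h_params)
        a2 = self.make_path(h_params.site_xy[0], weight=0.1)
        b2 = self.make_path(h_params.site_xy[1], weight=0.3)
        d2 = pw.contact_distribution([a2, b2], h_params)
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-12)


class TestClassProbabilities:
    def path_with_class(self, cid, weight):
        f = np.zeros((2, 2))
        p = Pathway(frames=f, frames_all=f, weight=weight,
                    start_iteration=1, end_iteration=2)
        p.class_id = cid
        return p

    def test_single_class(self):
        paths = [self.path_with_class(1, 0.4)]
        assert pw.class_probabilities(paths) == {1: 1.0}

    def test_three_to_one_split(self):
        paths = [self.path_with_class(1, 0.1) for _ in range(3)]
        paths.append(self.path_with_class(2, 0.1))
        probs = pw.class_probabilities(paths)
        assert probs[1] == pytest.approx(0.75)
        assert probs[2] == pytest.approx(0.25)

    def test_uniform_rescaling_invariant(self):
        paths = [self.path_with_class(1, 0.3), self.path_with_class(2, 0.6)]
        scaled = [self.path_with_class(1, 3.0), self.path_with_class(2, 6.0)]
        assert pw.class_probabilities(paths) == pytest.approx(
            pw.class_probabilities(scaled))

    def test_unclassed_pathway_rejected(self):
        f = np.zeros((2, 2))
        p = Pathway(frames=f, frames_all=f, weight=1.0,
                    start_iteration=1, end_iteration=2)
        with pytest.raises(ValueError, match="class id"):
            pw.class_probabilities([p])


class TestAdditionSite:
    def test_final_approach_angle_selects_site(self, h_params):
        for k, (angle, lab) in enumerate(zip(h_params.site_angles,
                                             h_params.site_labels)):
            xy = 1.0 * np.array([np.cos(angle + 0.05), np.sin(angle + 0.05)])
            frames = np.array([[8.0, 0.0], xy])
            p = Pathway(frames=frames, frames_all=frames, weight=1.0,
                        start_iteration=1, end_iteration=2)
            assert pw.addition_site(p, h_params) == lab
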