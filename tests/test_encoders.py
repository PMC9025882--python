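"""Encoder worked examples, independent brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import m5csub as m
from m5csub.encoders import DINUCLEOTIDES, PCTable, get_encoder

RNA = st.text(alphabet="ACGU", min_size=5, max_size=25)
RNA_N = st.text(alphabet="ACGUN", min_size=5, max_size=25)

DI = {d: i for i, d in enumerate(DINUCLEOTIDES)}


# ---------------------------------------------------------------------------
# independent oracles (straight-from-definition double loops)


def oracle_property_profile(window, pc):
    """Per-property dinucleotide values; N-containing dinucleotides get the
    window mean of the valid values (zero deviation)."""
    dis = [window[j : j + 2] for j in range(len(window) - 1)]
    profile = np.empty((pc.n_properties, len(dis)))
    for i in range(pc.n_properties):
        vals = [pc.matrix[i, DI[d]] for d in dis if d in DI]
        mean = np.mean(vals) if vals else 0.0
        profile[i] = [pc.matrix[i, DI[d]] if d in DI else mean for d in dis]
    return profile


def oracle_autocov(window, pc, lag):
    profile = oracle_property_profile(window, pc)
    L1 = profile.shape[1]
    out = []
    for i in range(pc.n_properties):
        mean = profile[i].mean()
        for lam in range(1, min(lag, L1 - 1) + 1):
            total = 0.0
            for j in range(L1 - lam):
                total += (profile[i, j] - mean) * (profile[i, j + lam] - mean)
            out.append(total / (L1 - lam))
    return np.array(out)


def oracle_crosscov(window, pc, lag):
    profile = oracle_property_profile(window, pc)
    L1 = profile.shape[1]
    means = profile.mean(axis=1)
    out = []
    for i1 in range(pc.n_properties):
        for i2 in range(pc.n_properties):
            if i1 == i2:
                continue
            for lam in range(1, min(lag, L1 - 1) + 1):
                total = 0.0
                for j in range(L1 - lam):
                    total += (profile[i1, j] - means[i1]) * (
                        profile[i2, j + lam] - means[i2]
                    )
                out.append(total / (L1 - lam))
    return np.array(out)


def oracle_pseknc(window, pc, k, lam, w):
    from itertools import product

    kmers = ["".join(t) for t in product("ACGU", repeat=k)]
    counts = np.array(
        [sum(window[j : j + k] == km for j in range(len(window) - k + 1)) for km in kmers],
        dtype=float,
    )
    freqs = counts / counts.sum() if counts.sum() else counts
    H = np.zeros((pc.n_properties, len(window) - 1))
    for j in range(len(window) - 1):
        d = window[j : j + 2]
        if d in DI:
            H[:, j] = pc.matrix[:, DI[d]]
    thetas = []
    for j in range(1, lam + 1):
        vals = [
            np.mean((H[:, mm] - H[:, mm + j]) ** 2)
            for mm in range(len(window) - 1 - j)
        ]
        thetas.append(np.mean(vals))
    thetas = np.array(thetas)
    denom = freqs.sum() + w * thetas.sum()
    return np.concatenate([freqs, w * thetas]) / denom


# ---------------------------------------------------------------------------


class TestConposi:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("AAA", {"AA": 1.0}),
            ("GCAU", {"GC": 1 / 3, "CA": 1 / 3, "AU": 1 / 3}),
            ("ANAU", {"AU": 1.0}),  # N-containing dinucleotides excluded
        ],
    )
    def test_examples(self, window, expected):
        vec = m.encode_conposi(window)
        for d, i in DI.items():
            assert vec[i] == pytest.approx(expected.get(d, 0.0))

    def test_all_n_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            assert m.encode_conposi("NNN").sum() == 0.0

    @given(window=RNA)
    @settings(max_examples=50, deadline=None)
    def test_components_sum_to_one(self, window):
        assert m.encode_conposi(window).sum() == pytest.approx(1.0)


class TestPositionalCodes:
    def test_onehot_examples(self):
        assert m.encode_onehot("A").tolist() == [1, 0, 0, 0]
        assert m.encode_onehot("AU").tolist() == [1, 0, 0, 0, 0, 0, 0, 1]
        assert m.encode_onehot("N").tolist() == [0, 0, 0, 0]

    @given(window=RNA_N)
    @settings(max_examples=50, deadline=None)
    def test_onehot_block_sums(self, window):
        blocks = m.encode_onehot(window).reshape(-1, 4).sum(axis=1)
        expected = [0.0 if b == "N" else 1.0 for b in window]
        assert blocks.tolist() == expected

    def test_eiip_worked_example(self):
        assert m.encode_eiip("GCAU").tolist() == [0.0806, 0.1340, 0.1260, 0.1335]

    def test_eiip_padding_and_repeats(self):
        assert m.encode_eiip("N").tolist() == [0.0]
        assert m.encode_eiip("AA").tolist() == [0.1260, 0.1260]

    def test_chemprop_example(self):
        assert m.encode_chemprop("ACGU").tolist() == [1, 1, 1, 0, 1, 0, 1, 0, 0, 0, 0, 1]
        assert m.encode_chemprop("N").tolist() == [0, 0, 0]

    def test_chemprop_component_semantics(self):
        # triplet order (ring, amino/keto, hydrogen bond): the ring bit marks
        # purines A/G, the amino bit marks A/C, the weak-H-bond bit marks A/U
        for base in "ACGU":
            ring, amino, hbond = m.encode_chemprop(base)
            assert ring == (1 if base in "AG" else 0)
            assert amino == (1 if base in "AC" else 0)
            assert hbond == (1 if base in "AU" else 0)


class TestPsnp:
    def test_hand_counted_toy_frequencies(self):
        # pos {AAC, AAG}: position 1 all AA; position 2 is AC once, AG once
        # neg {CCA, CCG}: position 1 all CC; position 2 is CA once, CG once
        model = m.fit_psnp(["AAC", "AAG"], ["CCA", "CCG"])
        assert model.Z[DI["AA"], 0] == pytest.approx(1.0)
        assert model.Z[DI["CC"], 0] == pytest.approx(-1.0)
        assert model.Z[DI["AC"], 1] == pytest.approx(0.5)
        assert m.encode_psnp("AAC", model).tolist() == pytest.approx([1.0, 0.5])

    def test_identical_classes_give_zero_matrix(self):
        model = m.fit_psnp(["ACG", "GCA"], ["ACG", "GCA"])
        assert np.all(model.Z == 0)
        assert np.all(m.encode_psnp("ACG", model) == 0)

    def test_antisymmetry(self):
        pos, neg = ["ACGUA", "GGCAU", "AACGU"], ["UUUAC", "CGCGC"]
        a = m.fit_psnp(pos, neg).Z
        b = m.fit_psnp(neg, pos).Z
        assert np.array_equal(a, -b)

    def test_column_sums_zero_for_n_free_training(self):
        rng = np.random.default_rng(0)
        pos = ["".join(rng.choice(list("ACGU"), 9)) for _ in range(20)]
        neg = ["".join(rng.choice(list("ACGU"), 9)) for _ in range(20)]
        model = m.fit_psnp(pos, neg)
        assert np.allclose(model.Z.sum(axis=0), 0, atol=1e-12)
        assert np.all(np.abs(model.Z) <= 1)

    def test_n_dinucleotides_score_zero(self):
        model = m.fit_psnp(["AAC", "AAG"], ["CCA", "CCG"])
        assert m.encode_psnp("NNC", model).tolist() == [0.0, 0.0]

    def test_errors(self):
        with pytest.raises(ValueError):
            m.fit_psnp([], ["ACG"])
        with pytest.raises(ValueError):
            m.fit_psnp(["ACG"], ["ACGU"])
        model = m.fit_psnp(["AAC"], ["CCA"])
        with pytest.raises(ValueError):
            m.encode_psnp("ACGU", model)


class TestCovarianceEncoders:
    def test_hand_derived_lag1(self):
        # single property with per-position values (1, 3, 2), mean 2:
        # AC_1 = ((1-2)(3-2) + (3-2)(2-2)) / 2 = -0.5
        matrix = np.zeros((1, 16))
        matrix[0, DI["AA"]] = 1.0
        matrix[0, DI["AC"]] = 3.0
        matrix[0, DI["CA"]] = 2.0
        pc = PCTable(["p"], matrix, normalize=False)
        vec = m.encode_autocov("AACA", pc, lag=1)
        assert vec.tolist() == pytest.approx([-0.5])

    def test_constant_property_gives_zero(self):
        pc = PCTable(["p", "q"], np.vstack([np.full(16, 3.0), np.arange(16.0)]),
                     normalize=False)
        vec = m.encode_autocov("ACGUACG", pc, lag=3)
        assert np.all(vec[:3] == 0)  # constant property block

    def test_identical_property_rows_collapse_cc_to_ac(self, pc_table):
        row = pc_table.matrix[0]
        pc = PCTable(["a", "b"], np.vstack([row, row]), normalize=False)
        ac = m.encode_autocov("ACGUACGGA", pc, lag=3)[:3]
        cc = m.encode_crosscov("ACGUACGGA", pc, lag=3)[:3]
        assert cc == pytest.approx(ac.tolist())

    @given(window=st.text(alphabet="ACGUN", min_size=5, max_size=15),
           lag=st.integers(1, 4))
    @settings(max_examples=100, deadline=None)
    def test_autocov_matches_brute_force(self, pc_table, window, lag):
        got = m.encode_autocov(window, pc_table, lag)
        want = oracle_autocov(window, pc_table, lag)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-14)

    @given(window=st.text(alphabet="ACGU", min_size=5, max_size=9))
    @settings(max_examples=100, deadline=None)
    def test_crosscov_matches_brute_force(self, pc_table, window):
        got = m.encode_crosscov(window, pc_table, lag=2)
        want = oracle_crosscov(window, pc_table, lag=2)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-14)

    @given(window=RNA)
    @settings(max_examples=50, deadline=None)
    def test_autocov_invariant_under_profile_reversal(self, pc_table, window):
        """Auto-covariance is symmetric in lag direction: reversing the
        property profile along the window leaves every AC_lam unchanged."""

        def ac_of(profile):
            out = []
            for i in range(profile.shape[0]):
                dev = profile[i] - profile[i].mean()
                for lam in range(1, 4):
                    if lam > len(dev) - 1:
                        continue
                    out.append((dev[:-lam] * dev[lam:]).mean())
            return np.array(out)

        profile = oracle_property_profile(window, pc_table)
        assert np.allclose(ac_of(profile), ac_of(profile[:, ::-1]), rtol=1e-9, atol=1e-12)

    def test_too_short_window_errors(self, pc_table):
        with pytest.raises(ValueError):
            m.encode_autocov("AC", pc_table, lag=1)


class TestPseknc:
    def test_components_sum_to_one(self, pc_table):
        window = "ACGUACGGAUCCGAUAGCUAGGGCAUCGAUA"
        assert m.encode_pseknc(window, pc_table).sum() == pytest.approx(1.0)

    def test_zero_weight_reduces_to_kmer_frequencies(self, pc_table):
        window = "ACGUACGGAUCCGAU"
        vec = m.encode_pseknc(window, pc_table, k=3, lam=2, w=1e-12)
        counts = np.zeros(64)
        from itertools import product

        kmers = {"".join(t): i for i, t in enumerate(product("ACGU", repeat=3))}
        for j in range(len(window) - 2):
            counts[kmers[window[j : j + 3]]] += 1
        assert np.allclose(vec[:64], counts / counts.sum(), atol=1e-9)
        assert np.allclose(vec[64:], 0, atol=1e-9)

    def test_matches_independent_formula(self, pc_table):
        rng = np.random.default_rng(42)
        window = "".join(rng.choice(list("ACGU"), 31))
        got = m.encode_pseknc(window, pc_table, k=3, lam=5, w=0.05)
        want = oracle_pseknc(window, pc_table, 3, 5, 0.05)
        assert np.allclose(got, want, rtol=1e-12)

    def test_too_short_errors(self, pc_table):
        with pytest.raises(ValueError):
            m.encode_pseknc("ACGUACG", pc_table, k=3, lam=5)


class TestCombineAndDims:
    def test_combination_additivity(self):
        window = "A" * 41
        combined = m.combine_features(m.encode_eiip(window), m.encode_conposi(window))
        assert combined.shape == (41 + 16,)

    def test_single_input_identity(self):
        v = m.encode_eiip("ACGU")
        assert np.array_equal(m.combine_features(v), v)

    def test_order_permutes_values(self):
        a, b = m.encode_eiip("ACGU"), m.encode_conposi("ACGU")
        ab = m.combine_features(a, b)
        ba = m.combine_features(b, a)
        assert sorted(ab.tolist()) == sorted(ba.tolist())

    @pytest.mark.parametrize("length", [21, 41, 81])
    @pytest.mark.parametrize(
        "scheme,dim_fn",
        [
            ("conposi", lambda L, lam: 16),
            ("onehot", lambda L, lam: 4 * L),
            ("psnp", lambda L, lam: L - 1),
            ("eiip", lambda L, lam: L),
            ("chemprop", lambda L, lam: 3 * L),
            ("autocov", lambda L, lam: 10 * lam),
            ("crosscov", lambda L, lam: 90 * lam),
            ("pseknc", lambda L, lam: 4**3 + 5),
        ],
    )
    def test_dimension_contract(self, scheme, dim_fn, length, pc_table):
        rng = np.random.default_rng(1)
        window = "".join(rng.choice(list("ACGU"), length))
        enc = m.get_encoder(scheme, pc_table)
        if enc.trainable:
            other = "".join(rng.choice(list("ACGU"), length))
            enc.fit([window], [other])
        lam = min(39, length - 2)
        assert enc.encode(window).shape == (dim_fn(length, lam),)
        assert enc.dim(length) == dim_fn(length, lam)

    def test_encoders_are_deterministic(self, pc_table):
        rng = np.random.default_rng(2)
        window = "".join(rng.choice(list("ACGU"), 41))
        for scheme in m5csub_schemes():
            enc = m.get_encoder(scheme, pc_table)
            if enc.trainable:
                enc.fit([window], [window[::-1]])
            a, b = enc.encode(window), enc.encode(window)
            assert np.array_equal(a, b), scheme


def m5csub_schemes():
    from m5csub.encoders import SCHEME_NAMES

    return SCHEME_NAMES


class TestPCTable:
    def test_standardization(self, pc_table):
        assert np.allclose(pc_table.matrix.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(pc_table.matrix.std(axis=1), 1, atol=1e-12)
        assert pc_table.n_properties == 10

    def test_tsv_round_trip(self, tmp_path, pc_table):
        path = tmp_path / "pc.tsv"
        with open(path, "w") as fh:
            fh.write("property\t" + "\t".join(DINUCLEOTIDES) + "\n")
            fh.write("p1\t" + "\t".join(str(v) for v in range(16)) + "\n")
        table = PCTable.from_tsv(str(path), normalize=False)
        assert table.matrix.tolist() == [list(map(float, range(16)))]
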