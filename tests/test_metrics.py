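import numpy as np
import pytest

from minimask import metrics
from minimask.fixtures import make_confidence_fixture
from minimask.helixtools import make_ideal_helix
from minimask.structio import Atom, Chain, ChainRole, Residue, Structure

from oracles import brute_force_contacts, quaternion_rmsd


def _ca_chain(chain_id, coords, role=ChainRole.UNASSIGNED, start=1):
    residues = [
        Residue(start + i, "ALA", [Atom("CA", "C", c)]) for i, c in enumerate(coords)
    ]
    return Chain(chain_id, residues, role=role)


def _line_chain(chain_id, n, origin, step=(4.0, 0, 0), role=ChainRole.UNASSIGNED):
    coords = [np.asarray(origin, float) + i * np.asarray(step, float) for i in range(n)]
    return _ca_chain(chain_id, coords, role)


class TestInterface:
    def test_distant_chains_have_empty_interface(self):
        st = Structure([_line_chain("A", 5, (0, 0, 0)), _line_chain("B", 5, (0, 500, 0))])
        rep = metrics.interface_residues(st, "A", "B", 5.0)
        assert rep.residues_a == set() and rep.residues_b == set() and rep.n_pairs == 0

    def test_parallel_helices_match_brute_force(self):
        """Two ideal helices 6 A apart: contact sets equal the all-pairs oracle."""
        h1 = make_ideal_helix(18, chain_id="A").chains[0]
        h2 = make_ideal_helix(18, axis_origin=(6.0, 0, 0), chain_id="B").chains[0]
        st = Structure([h1, h2])
        rep = metrics.interface_residues(st, "A", "B", 5.0)
        oa, ob, pairs = brute_force_contacts(st, "A", "B", 5.0)
        assert rep.residues_a == oa
        assert rep.residues_b == ob
        assert rep.n_pairs == len(pairs)
        assert rep.n_pairs > 0

    def test_symmetry(self, one_fixture):
        st = one_fixture.binder_mask
        ab = metrics.interface_residues(st, "A", "M", 5.0)
        ba = metrics.interface_residues(st, "M", "A", 5.0)
        assert ab.residues_a == {("A", i) for _, i in ba.residues_b}
        assert ab.residues_b == {("M", i) for _, i in ba.residues_a}

    def test_missing_chain_raises(self, one_fixture):
        with pytest.raises(KeyError):
            metrics.interface_residues(one_fixture.binder_mask, "A", "Z", 5.0)

    def test_default_cutoff_is_5A(self, one_fixture):
        st = one_fixture.binder_mask
        assert metrics.interface_residues(st, "A", "M").contact_cutoff == 5.0


class TestCoverage:
    def _models(self, n_blocked):
        """21 interface residues in a line, a mask line blocking the first n."""
        binder = _line_chain("A", 21, (0, 0, 0), role=ChainRole.BINDER)
        receptor = _line_chain("R", 21, (0, 4.0, 0), role=ChainRole.RECEPTOR)
        mask_coords = [(4.0 * i, -4.0, 0.0) for i in range(n_blocked)]
        mask = _ca_chain("M", [np.array(c) for c in mask_coords], role=ChainRole.MASK)
        br = Structure([binder, receptor])
        binder2 = _line_chain("A", 21, (0, 0, 0), role=ChainRole.BINDER)
        bm = Structure([binder2, mask])
        return br, bm

    def test_fifteen_of_twentyone_blocked(self):
        """A mask reaching 15 of 21 interface residues gives coverage 15/21."""
        br, bm = self._models(15)
        cov = metrics.mask_coverage(br, bm, cutoff=5.0)
        assert len(cov.interface_residues) == 21
        assert len(cov.blocked_residues) == 15
        assert cov.coverage == pytest.approx(15 / 21)

    def test_far_mask_gives_zero(self):
        br, bm = self._models(21)
        far = Structure(
            [bm.chain("A"),
             _line_chain("M", 5, (0, -200.0, 0), role=ChainRole.MASK)]
        )
        assert metrics.mask_coverage(br, far).coverage == 0.0

    def test_empty_interface_flagged_not_fatal(self):
        binder = _line_chain("A", 5, (0, 0, 0), role=ChainRole.BINDER)
        receptor = _line_chain("R", 5, (0, 400, 0), role=ChainRole.RECEPTOR)
        mask = _line_chain("M", 5, (0, -4, 0), role=ChainRole.MASK)
        cov = metrics.mask_coverage(
            Structure([binder, receptor]), Structure([binder, mask])
        )
        assert cov.coverage == 0.0 and cov.empty_interface

    def test_binder_length_mismatch_rejected(self):
        br, _ = self._models(5)
        bad_bm = Structure(
            [_line_chain("A", 20, (0, 0, 0), role=ChainRole.BINDER),
             _line_chain("M", 5, (0, -4, 0), role=ChainRole.MASK)]
        )
        with pytest.raises(ValueError, match="length mismatch"):
            metrics.mask_coverage(br, bad_bm)

    def test_contact_sets_monotone_in_cutoff(self, one_fixture):
        """Interface and blocked sets only grow as the cutoff widens (the
        coverage ratio itself need not, since the denominator grows too)."""
        results = [
            metrics.mask_coverage(one_fixture.binder_receptor, one_fixture.binder_mask,
                                  cutoff=c)
            for c in (4.0, 5.0, 6.0, 8.0)
        ]
        for tight, loose in zip(results, results[1:]):
            assert tight.interface_residues <= loose.interface_residues
            assert tight.blocked_residues <= loose.blocked_residues


class TestOrientation:
    def test_clear_c_terminal_and_mirror(self):
        binder = _ca_chain("A", [np.array([0.0, 0, 0]), np.array([40.0, 0, 0])],
                           role=ChainRole.BINDER)
        mask_ct = _ca_chain("M", [np.array([45.0, 0, 0]), np.array([80.0, 0, 0])],
                            role=ChainRole.MASK)
        res = metrics.orientation_check(Structure([binder, mask_ct]))
        assert res.c_terminal_orientation and res.d_cterm == pytest.approx(5.0)
        mask_nt = _ca_chain("M", [np.array([80.0, 0, 0]), np.array([-5.0, 0, 0])],
                            role=ChainRole.MASK)
        assert not metrics.orientation_check(Structure([binder, mask_nt])).c_terminal_orientation

    def test_tie_resolves_as_false(self):
        binder = _ca_chain("A", [np.array([0.0, 0, 0]), np.array([10.0, 0, 0])],
                           role=ChainRole.BINDER)
        mask = _ca_chain("M", [np.array([15.0, 0, 0]), np.array([-5.0, 0, 0])],
                         role=ChainRole.MASK)
        assert not metrics.orientation_check(Structure([binder, mask])).c_terminal_orientation

    def test_random_fixtures_match_direct_comparison(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            b = rng.normal(0, 20, (4, 3))
            m = rng.normal(0, 20, (3, 3))
            binder = _ca_chain("A", list(b), role=ChainRole.BINDER)
            mask = _ca_chain("M", list(m), role=ChainRole.MASK)
            res = metrics.orientation_check(Structure([binder, mask]))
            d_ct = np.linalg.norm(b[-1] - m[0])
            d_nt = np.linalg.norm(b[0] - m[-1])
            assert res.c_terminal_orientation == (d_ct < d_nt)


class TestConfidenceMetrics:
    def test_constant_plddt_and_selections(self):
        conf = make_confidence_fixture([("A", 4), ("B", 3)], [90.0, 90.0], 5.0, 5.0, 0.0, 0)
        assert metrics.mean_plddt(conf, "all") == pytest.approx(90.0)
        assert metrics.mean_plddt(conf, [("B", 2)]) == pytest.approx(90.0)
        with pytest.raises(ValueError, match="empty"):
            metrics.mean_plddt(conf, [])
        with pytest.raises(KeyError):
            metrics.mean_plddt(conf, [("Z", 1)])

    def test_mean_plddt_matches_summation_oracle(self):
        rng = np.random.default_rng(3)
        conf = make_confidence_fixture([("A", 30), ("B", 20)], [85.0, 75.0], 4.0, 8.0, 2.0, 9)
        sel = [("A", int(i) + 1) for i in rng.choice(30, 10, replace=False)]
        positions = [i for i, key in enumerate(conf.residue_map) if key in set(sel)]
        oracle = sum(conf.plddt[i] for i in positions) / len(positions)
        assert metrics.mean_plddt(conf, sel) == pytest.approx(oracle, abs=1e-12)

    def test_interchain_pae_constant_and_blocks(self):
        conf = make_confidence_fixture([("A", 5), ("B", 5)], [90, 90], 8.0, 8.0, 0.0, 0)
        a = [("A", i + 1) for i in range(5)]
        b = [("B", i + 1) for i in range(5)]
        assert metrics.interchain_pae(conf, a, b) == pytest.approx(8.0)
        # equal-size blocks at 6 and 10 average to 8
        conf.pae[:5, 5:] = 6.0
        conf.pae[5:, :5] = 10.0
        assert metrics.interchain_pae(conf, a, b) == pytest.approx(8.0)

    def test_interchain_pae_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        conf = make_confidence_fixture([("A", 12), ("B", 9)], [90, 90], 5.0, 9.0, 1.5, 21)
        a = [("A", i + 1) for i in range(12)]
        b = [("B", i + 1) for i in range(9)]
        total, count = 0.0, 0
        lookup = {k: i for i, k in enumerate(conf.residue_map)}
        for ka in a:
            for kb in b:
                total += conf.pae[lookup[ka], lookup[kb]]
                total += conf.pae[lookup[kb], lookup[ka]]
                count += 2
        assert metrics.interchain_pae(conf, a, b) == pytest.approx(total / count, abs=1e-12)

    def test_overlapping_sets_rejected(self):
        conf = make_confidence_fixture([("A", 4), ("B", 4)], [90, 90], 5, 5, 0, 0)
        with pytest.raises(ValueError, match="overlap"):
            metrics.interchain_pae(conf, [("A", 1)], [("A", 1), ("B", 1)])


class TestKabsch:
    def test_identical_sets_rmsd_zero(self):
        a = np.random.default_rng(0).normal(0, 10, (12, 3))
        res = metrics.kabsch_superpose(a, a)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 10, (20, 3))
        angle = 1.1
        rot = np.array(
            [[np.cos(angle), -np.sin(angle), 0], [np.sin(angle), np.cos(angle), 0], [0, 0, 1]]
        )
        b = a @ rot.T + np.array([3.0, -7.0, 2.0])
        assert metrics.kabsch_superpose(a, b).rmsd <= 1e-8

    def test_matches_quaternion_oracle_on_random_pairs(self):
        """SVD Kabsch RMSD equals the quaternion-eigenvalue route to 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 51))
            a = rng.normal(0, 8, (n, 3))
            b = a + rng.normal(0, 1.0, (n, 3))
            assert metrics.kabsch_superpose(a, b).rmsd == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-8
            )

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 5, (10, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirror image: reflection must be corrected, not used
        res = metrics.kabsch_superpose(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="degenerate"):
            metrics.kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="at least 3"):
            metrics.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCaRmsd:
    def test_self_rmsd_zero(self, one_fixture):
        assert metrics.ca_rmsd(one_fixture.binder_mask, one_fixture.binder_mask) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_jittered_copy_matches_kabsch_on_extracted_coords(self, one_fixture):
        rng = np.random.default_rng(9)
        st = one_fixture.binder_mask
        jittered_chains = []
        coords_a, coords_b = [], []
        for ch in st.chains:
            new_res = []
            for r in ch.residues:
                jit = r.ca.coord + rng.normal(0, 0.5, 3)
                new_res.append(Residue(r.index, r.name, [Atom("CA", "C", jit)]))
                coords_a.append(r.ca.coord)
                coords_b.append(jit)
            jittered_chains.append(Chain(ch.id, new_res, role=ch.role))
        jittered = Structure(jittered_chains)
        oracle = metrics.kabsch_superpose(np.array(coords_a), np.array(coords_b)).rmsd
        assert metrics.ca_rmsd(st, jittered) == pytest.approx(oracle, abs=1e-10)

    def test_unpaired_residues_rejected(self, one_fixture):
        st = one_fixture.binder_mask
        shorter = Structure(
            [st.chains[0],
             Chain("M", st.chain("M").residues[:-2], role=ChainRole.MASK)]
        )
        with pytest.raises(ValueError, match="unpaired"):
            metrics.ca_rmsd(st, shorter)
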