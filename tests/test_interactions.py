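import numpy as np
import pytest

from thermotraj import interactions as ia
from thermotraj import synthetic as syn
from thermotraj.interactions import (
    HBondCriteria,
    ResidueRef,
    SaltBridgeObservation,
    StabilityClass,
)
from thermotraj.io_structures import AtomRecord, ReplicaSet, Topology, Trajectory
from thermotraj.published import load_saltbridge_table


def _obs(basic, acidic, f_mean, f_rep=None):
    return SaltBridgeObservation(
        basic_residue=basic,
        acidic_residue=acidic,
        r_max=4.0,
        presence=[],
        f_per_replica=np.asarray(f_rep if f_rep is not None else [f_mean]),
        f_mean=f_mean,
    )


def _ref(name, seq):
    return ResidueRef("A", seq, name)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _dha_topology():
    """Donor N (with H) in residue 1, acceptor O in residue 2."""
    atoms = [
        AtomRecord(1, "N", "N", "ALA", 1, "A", 14.007),
        AtomRecord(2, "H", "H", "ALA", 1, "A", 1.008),
        AtomRecord(3, "O", "O", "ALA", 2, "A", 15.999),
    ]
    return Topology(atoms)


def _dha_frame(d_da, theta_deg):
    """Collinear D-H with the acceptor at angle theta from the D->H axis."""
    t = np.radians(theta_deg)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [d_da * np.cos(t), d_da * np.sin(t), 0.0],
        ]
    )


class TestHBondFrame:
    def test_collinear_within_cutoffs_detected(self):
        top = _dha_topology()
        bonds = ia.detect_hbonds_frame(_dha_frame(2.9, 0.0), top)
        assert bonds == [(0, 1, 2)]

    def test_distance_rule(self):
        top = _dha_topology()
        assert ia.detect_hbonds_frame(_dha_frame(3.6, 0.0), top) == []
        assert ia.detect_hbonds_frame(_dha_frame(3.5, 0.0), top) == [(0, 1, 2)]

    def test_angle_rule(self):
        top = _dha_topology()
        assert ia.detect_hbonds_frame(_dha_frame(2.9, 35.0), top) == []
        assert ia.detect_hbonds_frame(_dha_frame(2.9, 29.9), top) == [(0, 1, 2)]

    def test_angle_at_hydrogen_convention(self):
        top = _dha_topology()
        crit = HBondCriteria(angle_at_hydrogen=True)
        # collinear D-H...A: angle at H is 180°, so 180-θ = 0 ≤ 30
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        assert ia.detect_hbonds_frame(frame, top, crit) == [(0, 1, 2)]

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(r_max=-1.0)
        with pytest.raises(ValueError):
            HBondCriteria(theta_max=95.0)

    def test_matches_brute_force_on_random_fixtures(self, strand8):
        wet = syn.add_water_shell(
            strand8,
            [
                {"residue_seq": 3, "atom": "N", "kind": "protein_donor"},
                {"residue_seq": 5, "atom": "O", "kind": "water_donor"},
            ],
            seed=1,
            n_random=3,
        )
        top = wet.topology
        crit = HBondCriteria()
        rng = np.random.default_rng(77)
        for trial in range(50):
            frame = wet.frames[0] + rng.normal(scale=0.7, size=wet.frames[0].shape)
            got = set(ia.detect_hbonds_frame(frame, top, crit))
            # independent O(n²) re-derivation with plain loops
            oracle = set()
            no_idx = [i for i, a in enumerate(top.atoms) if a.element in ("N", "O")]
            h_idx = [i for i, a in enumerate(top.atoms) if a.element == "H"]
            for d in no_idx:
                for h in h_idx:
                    if np.linalg.norm(frame[h] - frame[d]) > 1.25:
                        continue
                    for a in no_idx:
                        if a == d or top.atom_residue[a] == top.atom_residue[d]:
                            continue
                        v1 = frame[h] - frame[d]
                        v2 = frame[a] - frame[d]
                        dist = np.linalg.norm(v2)
                        if dist > 3.5:
                            continue
                        cosang = v1 @ v2 / (np.linalg.norm(v1) * dist)
                        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if ang <= 30.0:
                            oracle.add((d, h, a))
            assert got == oracle, f"trial {trial}"


class TestHBondSeries:
    def test_ps_requires_water(self, helix12):
        with pytest.raises(ValueError, match="water"):
            ia.hbond_series(helix12, "ps")

    def test_engineered_ps_count_static(self, strand8):
        wet = syn.add_water_shell(
            strand8,
            [
                {"residue_seq": 3, "atom": "N", "kind": "protein_donor"},
                {"residue_seq": 5, "atom": "O", "kind": "water_donor"},
                {"residue_seq": 7, "atom": "N", "kind": "protein_donor"},
            ],
            seed=2,
            n_random=4,
        )
        frames = np.repeat(wet.frames, 3, axis=0)
        traj = Trajectory(wet.topology, frames)
        counts = ia.hbond_series(traj, "ps")
        assert list(counts.counts) == [3, 3, 3]

    def test_pp_on_ideal_helix(self, helix12):
        # i -> i+4 backbone bonds: residues 4..11 donate to 0..7
        counts = ia.hbond_series(helix12, "pp")
        assert counts.counts[0] == 8

    def test_pp_and_ps_disjoint(self, strand8):
        wet = syn.add_water_shell(
            strand8,
            [{"residue_seq": 4, "atom": "N", "kind": "protein_donor"}],
            seed=3,
        )
        pp = ia.hbond_series(wet, "pp").counts[0]
        ps = ia.hbond_series(wet, "ps").counts[0]
        total_bonds = len(
            ia.detect_hbonds_frame(wet.frames[0], wet.topology)
        )
        assert pp + ps <= total_bonds


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

class TestSaltBridgeFrame:
    def test_pair_within_cutoff_present(self):
        spec = syn.ToyProteinSpec(charge_pairs=[syn.ChargePair(2, "LYS", 15, "ASP", 3.8)])
        tp = syn.build_toy_protein(spec)
        pairs = ia.detect_salt_bridges_frame(tp.frames[0], tp.topology)
        assert {(p[0].name, p[1].name) for p in pairs} == {("LYS", "ASP")}

    def test_pair_beyond_cutoff_absent(self):
        spec = syn.ToyProteinSpec(charge_pairs=[syn.ChargePair(2, "LYS", 15, "ASP", 4.1)])
        tp = syn.build_toy_protein(spec)
        assert ia.detect_salt_bridges_frame(tp.frames[0], tp.topology) == set()

    def test_cutoff_monotonicity(self, toy_protein):
        frame = toy_protein.frames[0]
        top = toy_protein.topology
        smaller = ia.detect_salt_bridges_frame(frame, top, r_max=3.0)
        larger = ia.detect_salt_bridges_frame(frame, top, r_max=4.0)
        assert smaller <= larger

    def test_matches_brute_force_on_shuffled_fixture(self):
        rng = np.random.default_rng(123)
        pairs = [
            syn.ChargePair(1, "LYS", 14, "ASP", 3.5),
            syn.ChargePair(4, "ARG", 17, "GLU", 5.0),
            syn.ChargePair(8, "LYS", 20, "GLU", 3.9),
        ]
        tp = syn.build_toy_protein(syn.ToyProteinSpec(charge_pairs=pairs))
        top = tp.topology
        basic_names = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
        acidic_names = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
        for trial in range(50):
            frame = tp.frames[0] + rng.normal(scale=1.0, size=tp.frames[0].shape)
            got = {
                (p[0].seq, p[1].seq)
                for p in ia.detect_salt_bridges_frame(frame, top)
            }
            oracle = set()
            for bi, bres in enumerate(top.residues):
                if bres.residue_name not in basic_names:
                    continue
                b_atoms = top.residue_atoms(bi, basic_names[bres.residue_name])
                for ai, ares in enumerate(top.residues):
                    if ares.residue_name not in acidic_names:
                        continue
                    a_atoms = top.residue_atoms(ai, acidic_names[ares.residue_name])
                    dmin = min(
                        np.linalg.norm(frame[x] - frame[y])
                        for x in b_atoms
                        for y in a_atoms
                    )
                    if dmin <= 4.0:
                        oracle.add((bres.residue_seq, ares.residue_seq))
            assert got == oracle, f"trial {trial}"


class TestSaltBridgeFrequencies:
    def test_constructed_fraction_exact(self, toy_protein):
        traj = syn.make_contact_trajectory(toy_protein, (2, 15), 0.30, 100, seed=5)
        obs = ia.salt_bridge_frequencies(ReplicaSet(302.0, [traj]))
        target = [
            o for o in obs
            if o.basic_residue.seq == 3 and o.acidic_residue.seq == 16
        ]
        assert len(target) == 1
        assert target[0].f_mean == pytest.approx(0.300, abs=1e-12)

    def test_replica_mean_is_arithmetic(self, toy_protein):
        replicas = [
            syn.make_contact_trajectory(toy_protein, (2, 15), p, 100, seed=s)
            for p, s in ((0.2, 1), (0.3, 2), (0.4, 3))
        ]
        obs = ia.salt_bridge_frequencies(ReplicaSet(302.0, replicas))
        target = [
            o for o in obs
            if o.basic_residue.seq == 3 and o.acidic_residue.seq == 16
        ][0]
        np.testing.assert_allclose(sorted(target.f_per_replica), [0.2, 0.3, 0.4])
        assert target.f_mean == pytest.approx(0.300, abs=1e-12)

    def test_never_present_pair_omitted(self, toy_protein):
        traj = syn.make_contact_trajectory(toy_protein, (2, 15), 0.0, 50, seed=4)
        # move the second engineered pair far apart too
        frames = traj.frames.copy()
        top = traj.topology
        ne = top.residue_atoms(6, ["NE"])[0]
        frames[:, ne] += 50.0
        obs = ia.salt_bridge_frequencies(ReplicaSet(302.0, [Trajectory(top, frames)]))
        assert obs == []

    def test_empty_replica_list_rejected(self):
        with pytest.raises(ValueError):
            ReplicaSet(302.0, [])


class TestStabilityClass:
    def test_paper_worked_example_high(self):
        assert ia.classify_stability(0.885) is StabilityClass.HIGH

    @pytest.mark.parametrize(
        "f,expected",
        [
            (0.75, StabilityClass.HIGH),
            (0.50, StabilityClass.MODERATE),
            (0.30, StabilityClass.LOW),
            (0.29, StabilityClass.NEGLIGIBLE),
            (0.0, StabilityClass.NEGLIGIBLE),
            (1.0, StabilityClass.HIGH),
        ],
    )
    def test_lower_inclusive_boundaries(self, f, expected):
        assert ia.classify_stability(f) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ia.classify_stability(1.2)
        with pytest.raises(ValueError):
            ia.classify_stability(-0.1)


class TestFormedPairs:
    def test_published_ecy_302K_has_eight(self):
        by_temp, _ = load_saltbridge_table("EcY")
        assert len(ia.formed_pairs(by_temp[302.0])) == 8

    def test_published_tmy_302K_has_fifteen(self):
        by_temp, _ = load_saltbridge_table("TmY")
        assert len(ia.formed_pairs(by_temp[302.0])) == 15

    def test_all_below_threshold_empty(self):
        obs = [_obs(_ref("LYS", 5), _ref("ASP", 9), 0.29) for _ in range(4)]
        assert ia.formed_pairs(obs) == []

    def test_ordering_descending_f(self):
        obs = [
            _obs(_ref("LYS", 5), _ref("ASP", 9), 0.4),
            _obs(_ref("LYS", 2), _ref("ASP", 7), 0.9),
        ]
        assert [o.f_mean for o in ia.formed_pairs(obs)] == [0.9, 0.4]

    def test_formed_pair_never_negligible(self):
        by_temp, _ = load_saltbridge_table("TmY")
        for temp, obs in by_temp.items():
            for o in ia.formed_pairs(obs):
                assert o.stability is not StabilityClass.NEGLIGIBLE


class TestNetworks:
    def test_ecy_networks(self):
        by_temp, _ = load_saltbridge_table("EcY")
        nets = ia.build_networks(ia.formed_pairs(by_temp[302.0]))
        motifs = sorted(n.motif for n in nets)
        assert motifs == ["dyad", "dyad", "dyad", "tetrad", "triad"]
        triad = next(n for n in nets if n.motif == "triad")
        assert {str(m) for m in triad.members} == {"ASP12", "LYS109", "ASP57"}
        tetrad = next(n for n in nets if n.motif == "tetrad")
        assert {str(m) for m in tetrad.members} == {"ARG22", "GLU35", "ARG18", "GLU37"}

    def test_tmy_networks(self):
        by_temp, _ = load_saltbridge_table("TmY")
        nets = ia.build_networks(ia.formed_pairs(by_temp[302.0]))
        motifs = sorted(n.motif for n in nets)
        assert motifs.count("triad") == 2
        assert motifs.count("tetrad") == 2
        assert motifs.count("dyad") == 5
        member_sets = [{str(m) for m in n.members} for n in nets]
        assert {"ASP9", "LYS104", "ASP54"} in member_sets
        assert {"GLU113", "ARG110", "ASP100", "LYS117"} in member_sets
        assert {"ASP64", "ARG37", "GLU68", "LYS71"} in member_sets
        assert {"ARG15", "GLU32", "LYS19"} in member_sets

    def test_empty_input_empty_output(self):
        assert ia.build_networks([]) == []

    def test_components_partition_residues(self):
        by_temp, _ = load_saltbridge_table("TmY")
        formed = ia.formed_pairs(by_temp[302.0])
        nets = ia.build_networks(formed)
        all_members = [m for n in nets for m in n.members]
        assert len(all_members) == len(set(all_members))
        in_pairs = {r for o in formed for r in o.pair}
        assert set(all_members) == in_pairs
        # components are connected: |edges| >= size - 1, equality iff acyclic
        for n in nets:
            assert len(n.edges) >= len(n.members) - 1


class TestLocality:
    def test_intra_same_element(self):
        ss_map = {("A", 20): "alpha1", ("A", 24): "alpha1"}
        assert ia.classify_locality((_ref("ASP", 20), _ref("LYS", 24)), ss_map) == "intra"

    def test_inter_different_elements(self):
        ss_map = {("A", 54): "beta3", ("A", 104): "beta5/alpha5"}
        assert ia.classify_locality((_ref("ASP", 54), _ref("LYS", 104)), ss_map) == "inter"

    def test_unmapped_residue_unassigned(self):
        ss_map = {("A", 20): "alpha1"}
        assert (
            ia.classify_locality((_ref("ASP", 20), _ref("LYS", 99)), ss_map)
            == "unassigned"
        )


class TestNonNativeBridges:
    def test_synthetic_emergence_flagged(self):
        pair = (_ref("LYS", 7), _ref("GLU", 34))
        by_temp = {
            302.0: [_obs(*pair, 0.10)],
            450.0: [_obs(*pair, 0.35)],
        }
        out = ia.detect_nonnative_bridges(by_temp, 302.0)
        assert len(out) == 1
        assert out[0]["formed_at"] == [(450.0, 0.35)]

    def test_published_ecy_emergent_pair(self):
        # Glu34-Lys7 emerges at 400 K (0.309) and 450 K (0.337)
        pair = (_ref("LYS", 7), _ref("GLU", 34))
        by_temp = {
            302.0: [_obs(*pair, 0.12)],
            328.0: [_obs(*pair, 0.20)],
            400.0: [_obs(*pair, 0.309)],
            450.0: [_obs(*pair, 0.337)],
        }
        out = ia.detect_nonnative_bridges(by_temp, 302.0)
        assert out[0]["formed_at"] == [(400.0, 0.309), (450.0, 0.337)]

    def test_native_pair_not_flagged(self):
        pair = (_ref("LYS", 104), _ref("ASP", 54))
        by_temp = {
            302.0: [_obs(*pair, 0.948)],
            450.0: [_obs(*pair, 0.885)],
        }
        assert ia.detect_nonnative_bridges(by_temp, 302.0) == []

    def test_missing_reference_temperature_rejected(self):
        with pytest.raises(ValueError):
            ia.detect_nonnative_bridges({450.0: []}, 302.0)
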