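"""C-terminus/target definitions and primary-pair priority selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neissdist.terminus_target import (
    ALPHA_N,
    TargetKind,
    all_pair_distances,
    euclidean,
    find_c_terminal,
    find_targets,
    round_report,
    select_primary_pair,
)

from conftest import backbone, make_chain

# ---------------------------------------------------------------------------
# independent oracle: literal walk down the published priority lists

LYS_ORDER = [("C", "NZ"), ("CA", "NZ"), ("N", "NZ"),
             ("C", "CA"), ("CA", "CA"), ("N", "CA"),
             ("C", "N"), ("CA", "N"), ("N", "N")]
NTERM_ORDER = [("C", ALPHA_N), ("CA", ALPHA_N), ("N", ALPHA_N),
               ("C", "CA"), ("CA", "CA"), ("N", "CA")]


def oracle_primary(kind, src_avail, tgt_avail, dist):
    """First available pair in the literal priority list; for an
    N-terminal lysine each of the first three ranks tries αN/Nε and keeps
    the shorter available one (tie -> αN)."""
    if kind is TargetKind.LYSINE:
        order = [[pair] for pair in LYS_ORDER]
    elif kind is TargetKind.N_TERMINUS:
        order = [[pair] for pair in NTERM_ORDER]
    else:
        order = [[("C", ALPHA_N), ("C", "NZ")],
                 [("CA", ALPHA_N), ("CA", "NZ")],
                 [("N", ALPHA_N), ("N", "NZ")],
                 [("C", "CA")], [("CA", "CA")], [("N", "CA")]]
    for rank, alternatives in enumerate(order, start=1):
        live = [(s, t) for s, t in alternatives
                if s in src_avail and t in tgt_avail]
        if not live:
            continue
        s, t = min(live, key=lambda p: dist[p])
        return (s, t, dist[(s, t)], rank)
    return None


def _geometry(kind, src_avail, tgt_avail, rng):
    """Concrete residues realising an availability pattern."""
    src_atoms = {n: rng.uniform(-5, 5, 3) for n in src_avail}
    tgt_atoms = {}
    for n in tgt_avail:
        phys = "N" if n == ALPHA_N else n
        tgt_atoms[phys] = rng.uniform(5, 15, 3)
    names = {TargetKind.LYSINE: "LYS", TargetKind.N_TERMINAL_LYSINE: "LYS",
             TargetKind.N_TERMINUS: "ALA"}
    ct_chain = make_chain([("GLY", {"CA": (0, 0, 0)}), ("GLU", src_atoms)])
    first = (names[kind], tgt_atoms)
    if kind is TargetKind.LYSINE:
        tgt_chain = make_chain([("GLY", {"CA": (50, 50, 50)}), first],
                               label_asym="B", auth_asym="B", entity="2")
        site = find_targets(tgt_chain)[1]
    else:
        tgt_chain = make_chain([first], label_asym="B", auth_asym="B",
                               entity="2")
        (site,) = find_targets(tgt_chain)
    ct = find_c_terminal(ct_chain)
    return ct, site


TARGET_SETS = {
    TargetKind.LYSINE: ("NZ", "CA", "N"),
    TargetKind.N_TERMINUS: (ALPHA_N, "CA"),
    TargetKind.N_TERMINAL_LYSINE: (ALPHA_N, "NZ", "CA"),
}


@pytest.mark.parametrize("kind", list(TargetKind))
def test_priority_selection_matches_literal_oracle_exhaustively(kind):
    """Every atom-availability pattern agrees with the brute-force walk
    down the literal priority list."""
    rng = np.random.default_rng(20260101)
    tgt_atoms = TARGET_SETS[kind]
    n_checked = 0
    for src_mask in itertools.product([0, 1], repeat=3):
        src_avail = {a for a, m in zip(("C", "CA", "N"), src_mask) if m}
        for tgt_mask in itertools.product([0, 1], repeat=len(tgt_atoms)):
            tgt_avail = {a for a, m in zip(tgt_atoms, tgt_mask) if m}
            if not src_avail or not tgt_avail:
                continue
            ct, site = _geometry(kind, src_avail, tgt_avail, rng)
            assert set(ct.available_atoms) == src_avail
            assert set(site.available_atoms) == tgt_avail
            dist = {(s, t): euclidean(ct.available_atoms[s],
                                      site.available_atoms[t])
                    for s in src_avail for t in tgt_avail}
            expected = oracle_primary(kind, src_avail, tgt_avail, dist)
            got = select_primary_pair(ct, site)
            assert expected is not None and got is not None
            assert (got.source_atom, got.target_atom) == expected[:2]
            assert got.distance == pytest.approx(expected[2])
            assert got.priority_rank == expected[3]
            n_checked += 1
    assert n_checked == 7 * (2 ** len(tgt_atoms) - 1)


class TestFindCTerminal:
    def test_last_fully_resolved_residue(self):
        chain = make_chain([
            ("MET", backbone((0, 0, 0))),
            ("ALA", backbone((4, 0, 0))),
            ("LYS", backbone((8, 0, 0))),
        ])
        ct = find_c_terminal(chain)
        assert ct.residue.name == "LYS"
        assert set(ct.available_atoms) == {"C", "CA", "N"}

    def test_trailing_nonstandard_residue_is_skipped(self):
        chain = make_chain([
            ("ALA", backbone((0, 0, 0))),
            ("GLY", backbone((4, 0, 0))),
            ("LIG", {"C1": (8, 0, 0)}),
        ])
        ct = find_c_terminal(chain)
        assert ct.residue.name == "GLY"

    def test_partial_resolution_restricts_available_atoms(self):
        chain = make_chain([
            ("ALA", backbone((0, 0, 0))),
            ("GLY", {"CA": (4, 0, 0)}),
        ])
        ct = find_c_terminal(chain)
        assert ct.residue.name == "GLY"
        assert set(ct.available_atoms) == {"CA"}

    def test_no_standard_residue_returns_none(self):
        chain = make_chain([("LIG", {"C1": (0, 0, 0)})])
        assert find_c_terminal(chain) is None


class TestFindTargets:
    def test_plain_chain_has_only_the_n_terminus(self):
        chain = make_chain([
            ("ALA", backbone((0, 0, 0))),
            ("GLY", backbone((4, 0, 0))),
            ("SER", backbone((8, 0, 0))),
        ])
        (site,) = find_targets(chain)
        assert site.kind is TargetKind.N_TERMINUS
        assert site.residue.name == "ALA"
        assert ALPHA_N in site.available_atoms

    def test_n_terminal_lysine_plus_internal_lysine(self):
        chain = make_chain([
            ("LYS", backbone((0, 0, 0), with_lysine_nz=(0, -4, 0))),
            ("ALA", backbone((4, 0, 0))),
            ("LYS", backbone((8, 0, 0), with_lysine_nz=(8, -4, 0))),
        ])
        first, internal = find_targets(chain)
        assert first.kind is TargetKind.N_TERMINAL_LYSINE
        assert {ALPHA_N, "NZ"} <= set(first.available_atoms)
        assert internal.kind is TargetKind.LYSINE
        assert "NZ" in internal.available_atoms
        assert ALPHA_N not in internal.available_atoms

    def test_unresolved_backbone_n_drops_alpha_amine(self):
        chain = make_chain([("ALA", {"CA": (0, 0, 0), "C": (1.5, 0, 0)})])
        (site,) = find_targets(chain)
        assert site.kind is TargetKind.N_TERMINUS
        assert set(site.available_atoms) == {"CA"}


class TestEuclidean:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 0, 0), (3, 4, 0), 5.0),
        ((1, 2, 3), (1, 2, 3), 0.0),
        ((1, 1, 1), (2, 2, 2), math.sqrt(3)),
    ])
    def test_known_values(self, a, b, expected):
        assert euclidean(a, b) == pytest.approx(expected, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            euclidean((0, 0, float("nan")), (1, 1, 1))


class TestAllPairDistances:
    def _pair(self, src_atoms, tgt_residue):
        ct_chain = make_chain([("GLU", src_atoms)])
        tgt_chain = make_chain(tgt_residue[0], label_asym="B", auth_asym="B",
                               entity="2")
        ct = find_c_terminal(ct_chain)
        site = find_targets(tgt_chain)[tgt_residue[1]]
        return ct, site

    def test_full_ct_and_internal_lysine_gives_nine(self):
        ct, site = self._pair(
            backbone((0, 0, 0)),
            ([("GLY", backbone((20, 0, 0))),
              ("LYS", backbone((24, 0, 0), with_lysine_nz=(24, -4, 0)))], 1))
        assert len(all_pair_distances(ct, site)) == 9

    def test_full_ct_and_n_terminal_nonlysine_gives_six(self):
        # αN and the backbone N of the first residue are one physical atom
        ct, site = self._pair(
            backbone((0, 0, 0)),
            ([("ALA", backbone((20, 0, 0)))], 0))
        pairs = all_pair_distances(ct, site)
        assert len(pairs) == 6
        assert {t for _, t, _ in pairs} == {ALPHA_N, "CA"}

    def test_single_atom_each_side_gives_one(self):
        ct, site = self._pair(
            {"CA": (0, 0, 0)},
            ([("GLY", backbone((20, 0, 0))),
              ("LYS", {"NZ": (24, -4, 0)})], 1))
        assert all_pair_distances(ct, site) == [
            ("CA", "NZ", pytest.approx(euclidean((0, 0, 0), (24, -4, 0))))]


class TestSelectPrimaryPair:
    def test_fully_resolved_lysine_takes_c_to_nz(self):
        ct_chain = make_chain([("GLU", backbone((0, 0, 0)))])
        tgt = make_chain([("GLY", backbone((20, 0, 0))),
                          ("LYS", backbone((24, 0, 0), with_lysine_nz=(24, -4, 0)))],
                         label_asym="B", auth_asym="B", entity="2")
        got = select_primary_pair(find_c_terminal(ct_chain),
                                  find_targets(tgt)[1])
        assert (got.source_atom, got.target_atom, got.priority_rank) == (
            "C", "NZ", 1)

    def test_missing_source_atoms_fall_back_in_order(self):
        ct_chain = make_chain([("GLU", {"N": (0, 0, 0)})])
        tgt = make_chain([("GLY", backbone((20, 0, 0))),
                          ("LYS", {"NZ": (24, -4, 0)})],
                         label_asym="B", auth_asym="B", entity="2")
        got = select_primary_pair(find_c_terminal(ct_chain),
                                  find_targets(tgt)[1])
        assert (got.source_atom, got.target_atom, got.priority_rank) == (
            "N", "NZ", 3)

    def test_unresolved_nz_falls_to_c_to_ca(self):
        ct_chain = make_chain([("GLU", backbone((0, 0, 0)))])
        tgt = make_chain([("GLY", backbone((20, 0, 0))),
                          ("LYS", {"CA": (24, 0, 0)})],
                         label_asym="B", auth_asym="B", entity="2")
        got = select_primary_pair(find_c_terminal(ct_chain),
                                  find_targets(tgt)[1])
        assert (got.source_atom, got.target_atom, got.priority_rank) == (
            "C", "CA", 4)

    def test_n_terminal_lysine_prefers_shorter_of_alpha_and_epsilon(self):
        ct_chain = make_chain([("GLU", {"C": (0, 0, 0)})])
        tgt = make_chain([("LYS", {"N": (5, 0, 0), "NZ": (4, 0, 0)})],
                         label_asym="B", auth_asym="B", entity="2")
        got = select_primary_pair(find_c_terminal(ct_chain),
                                  find_targets(tgt)[0])
        assert (got.source_atom, got.target_atom) == ("C", "NZ")
        assert got.distance == pytest.approx(4.0)

    def test_n_terminal_lysine_exact_tie_goes_to_alpha_amine(self):
        ct_chain = make_chain([("GLU", {"C": (0, 0, 0)})])
        tgt = make_chain([("LYS", {"N": (0, 4, 0), "NZ": (4, 0, 0)})],
                         label_asym="B", auth_asym="B", entity="2")
        got = select_primary_pair(find_c_terminal(ct_chain),
                                  find_targets(tgt)[0])
        assert got.target_atom == ALPHA_N

    def test_priority_beats_minimality(self):
        # d(C, NZ) > d(CA, NZ), yet C-NZ is chosen: the order is a
        # priority list, not a minimum
        ct_chain = make_chain([("GLU", {"C": (0, 0, 0), "CA": (9, 0, 0)})])
        tgt = make_chain([("GLY", backbone((30, 0, 0))),
                          ("LYS", {"NZ": (10, 0, 0)})],
                         label_asym="B", auth_asym="B", entity="2")
        ct = find_c_terminal(ct_chain)
        site = find_targets(tgt)[1]
        got = select_primary_pair(ct, site)
        assert (got.source_atom, got.target_atom) == ("C", "NZ")
        dists = dict(((s, t), d) for s, t, d in all_pair_distances(ct, site))
        assert got.distance > dists[("CA", "NZ")]


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_rigid_transform_leaves_all_distances_unchanged(seed):
    rng = np.random.default_rng(seed)
    src = {n: rng.uniform(-5, 5, 3) for n in ("C", "CA", "N")}
    nz = rng.uniform(5, 10, 3)
    ct_chain = make_chain([("GLU", src)])
    tgt = make_chain([("GLY", backbone((30, 0, 0))),
                      ("LYS", backbone((34, 0, 0), with_lysine_nz=nz))],
                     label_asym="B", auth_asym="B", entity="2")
    # random proper rotation (QR with positive determinant) + translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-100, 100, 3)

    def moved(chain):
        for res in chain.residues:
            for atom in res.atoms.values():
                atom.coords = q @ atom.coords + t
        return chain

    before = all_pair_distances(find_c_terminal(ct_chain),
                                find_targets(tgt)[1])
    after = all_pair_distances(find_c_terminal(moved(ct_chain)),
                               find_targets(moved(tgt))[1])
    for (s1, t1, d1), (s2, t2, d2) in zip(before, after):
        assert (s1, t1) == (s2, t2)
        assert d2 == pytest.approx(d1, rel=1e-6)


@pytest.mark.parametrize("value,ndigits,expected", [
    (3.45, 1, 3.5),       # half rounds away from zero
    (16.84, 1, 16.8),
    (13.5, 0, 14.0),
    (14.49, 0, 14.0),
])
def test_report_rounding_half_away(value, ndigits, expected):
    assert round_report(value, ndigits) == pytest.approx(expected)
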