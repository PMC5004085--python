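"""Family construction, size tables, missing-member attribution, ensembles."""

import numpy as np
import pytest

from famscape.family_analysis import (
    Family,
    attribute_missing,
    build_families,
    select_ensembles,
    tabulate_sizes,
)
from famscape.gridspace import (
    GridSpec,
    InstanceRecord,
    ParameterPoint,
    VARIED_FRACTIONS,
    VARIED_PARAMS,
)
from famscape.synthetic_data import make_synthetic_db

BASE = ParameterPoint(1, 1, 1, 1, 1, 1, 1, -60.0)
DEFAULT_SPEC = GridSpec()


def rec(point, label="rHCO", **kw):
    return InstanceRecord(point=point, label=label, **kw)


class TestBuildFamilies:
    def test_three_members_one_noninterrupted_family(self):
        group = [rec(BASE.replace(x_h=v)) for v in (0.25, 0.5, 0.75)]
        fams = build_families(group, "x_h", DEFAULT_SPEC)
        assert len(fams) == 1
        fam = fams[0]
        assert fam.members == (0.25, 0.5, 0.75)
        assert not fam.interrupted
        assert fam.missing_outside == (0.0, 1.0, 1.25, 1.5, 1.75)

    def test_gap_marks_interruption(self):
        group = [rec(BASE.replace(x_h=v)) for v in (0.0, 0.25, 0.75)]
        (fam,) = build_families(group, "x_h", DEFAULT_SPEC)
        assert fam.interrupted
        assert fam.missing_inside == (0.5,)
        assert fam.missing_outside == (1.0, 1.25, 1.5, 1.75)

    def test_singletons_are_noninterrupted(self):
        group = [rec(BASE), rec(BASE.replace(x_K2=0.5, x_h=0.25))]
        fams = build_families(group, "x_h", DEFAULT_SPEC)
        assert len(fams) == 2
        assert all(f.size == 1 and not f.interrupted for f in fams)

    def test_off_grid_instance_rejected(self):
        group = [rec(BASE.replace(x_h=0.33))]
        with pytest.raises(ValueError, match="grid level"):
            build_families(group, "x_h", DEFAULT_SPEC)

    def test_partition_of_members_missing_levels(self):
        group = [rec(BASE.replace(x_h=v)) for v in (0.25, 0.75, 1.75)]
        (fam,) = build_families(group, "x_h", DEFAULT_SPEC)
        combined = sorted(fam.members + fam.missing_inside + fam.missing_outside)
        assert tuple(combined) == DEFAULT_SPEC.x_h

    def test_matches_pairwise_difference_oracle(self, toy_spec, toy_db):
        """Grouping equals O(N^2) 'differ in exactly one parameter' clustering."""
        rhcos = [r for r in toy_db if r.label == "rHCO"]
        rng = np.random.default_rng(0)
        sample = [rhcos[i] for i in rng.choice(len(rhcos), size=min(400, len(rhcos)),
                                               replace=False)]
        for defining in ("x_h", "x_CaS"):
            fams = build_families(sample, defining, toy_spec)
            got = {frozenset(f.member_point(v) for v in f.members) for f in fams}
            # oracle: union-find over pairs differing only in `defining`
            parent = list(range(len(sample)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(sample)):
                for j in range(i + 1, len(sample)):
                    pi, pj = sample[i].point, sample[j].point
                    diffs = [p for p in VARIED_PARAMS if pi.get(p) != pj.get(p)]
                    if diffs == [defining]:
                        parent[find(i)] = find(j)
            clusters = {}
            for i in range(len(sample)):
                clusters.setdefault(find(i), set()).add(sample[i].point)
            want = {frozenset(c) for c in clusters.values()}
            assert got == want


class TestTabulateSizes:
    def test_partition_identity_on_synthetic_db(self, toy_spec, toy_db):
        rhcos = [r for r in toy_db if r.label == "rHCO"]
        for param in VARIED_PARAMS:
            table = tabulate_sizes(build_families(rhcos, param, toy_spec))
            assert table.group_size() == len(rhcos)

    def test_empty_group(self):
        table = tabulate_sizes([])
        assert table.total == {} and table.group_size() == 0

    def test_single_full_family(self):
        group = [rec(BASE.replace(x_h=v)) for v in DEFAULT_SPEC.x_h]
        table = tabulate_sizes(build_families(group, "x_h", DEFAULT_SPEC))
        assert table.total == {8: 1}
        assert table.noninterrupted == {8: 1}

    def test_noninterrupted_bounded_by_total(self, toy_spec, toy_db):
        fhcos = [r for r in toy_db if r.label == "fHCO"]
        table = tabulate_sizes(build_families(fhcos, "x_h", toy_spec))
        for s in table.sizes():
            assert table.noninterrupted.get(s, 0) <= table.total[s]


class TestAttributeMissing:
    def test_fhco_gap_binned_by_failed_criterion(self):
        group = [rec(BASE.replace(x_h=v)) for v in (0.25, 0.5, 1.0)]
        (fam,) = build_families(group, "x_h", DEFAULT_SPEC)
        full = {r.point: r for r in group}
        gap = BASE.replace(x_h=0.75)
        full[gap] = rec(gap, label="fHCO", fail_flags="--D")
        for v in fam.missing_outside:
            p = BASE.replace(x_h=v)
            full[p] = rec(p, label="silent")
        attribution = attribute_missing([fam], full)
        inside = [m for m in attribution.members if m.inside]
        assert len(inside) == 1
        assert inside[0].label == "fHCO" and inside[0].category == "duty cycle"
        assert attribution.by_label()["silent"] == len(fam.missing_outside) == 4

    def test_missing_point_absent_from_db_raises(self):
        group = [rec(BASE.replace(x_h=v)) for v in (0.25, 0.75)]
        (fam,) = build_families(group, "x_h", DEFAULT_SPEC)
        with pytest.raises(KeyError, match="absent"):
            attribute_missing([fam], {r.point: r for r in group})

    def test_every_missing_member_attributed_once(self, toy_spec, toy_db):
        rhcos = [r for r in toy_db if r.label == "rHCO"][:200]
        fams = build_families(rhcos, "x_h", toy_spec)
        attribution = attribute_missing(fams, toy_db)
        expected = sum(len(f.missing_inside) + len(f.missing_outside) for f in fams)
        assert len(attribution.members) == expected


class TestSelectEnsembles:
    def _family(self, members, ctx_overrides=None):
        ctx_overrides = ctx_overrides or {}
        group = [rec(BASE.replace(x_h=v, **ctx_overrides)) for v in members]
        return build_families(group, "x_h", DEFAULT_SPEC)[0]

    def test_zero_context_conductance_excluded(self):
        fam = self._family((0.25, 0.5, 0.75, 1.0, 1.25), {"x_CaS": 0.0})
        assert select_ensembles([fam], None, min_members=4) == []

    def test_interrupted_family_excluded(self):
        fam = self._family((0.25, 0.5, 1.0, 1.25, 1.5))
        assert fam.interrupted
        assert select_ensembles([fam], None, min_members=4) == []

    def test_large_noninterrupted_family_kept(self):
        fam = self._family((0.25, 0.5, 0.75, 1.0, 1.25))
        assert select_ensembles([fam], None, min_members=4) == [fam]

    def test_isolated_filter_checks_synapse_free_counterparts(self):
        fam = self._family((0.25, 0.5, 0.75, 1.0, 1.25))
        full = {}
        for v in fam.members:
            iso = fam.member_point(v).replace(x_SynS=0.0, x_SynG=0.0)
            full[iso] = rec(iso, label="spiking")
        assert select_ensembles([fam], full, 4, isolated_filter="spiking") == [fam]
        # one counterpart with the wrong isolated activity disqualifies
        bad = fam.member_point(0.5).replace(x_SynS=0.0, x_SynG=0.0)
        full[bad] = rec(bad, label="silent")
        assert select_ensembles([fam], full, 4, isolated_filter="spiking") == []

    def test_unknown_filter_label_rejected(self):
        fam = self._family((0.25, 0.5, 0.75, 1.0, 1.25))
        with pytest.raises(ValueError, match="unknown filter label"):
            select_ensembles([fam], {}, 4, isolated_filter="wobbling")
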