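"""Targets, compound ingestion, descriptor backends and fingerprints."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from soacml.errors import FeaturizationError, SchemaError
from soacml.featurization import (CompoundRecord, StubDescriptorBackend,
                                  ToolkitDescriptorBackend, build_feature_tables,
                                  canonical_smiles, compute_descriptors,
                                  compute_fingerprint, compute_target,
                                  make_record, parse_quantum_listing,
                                  read_compounds, target_from_soac)


class TestTargets:
    def test_equal_rates_give_zero(self):
        assert compute_target(1.0e7, 1.0e7) == 0.0

    def test_rate_ratio_e_gives_one(self):
        assert compute_target(math.e * 3.2e6, 3.2e6) == pytest.approx(1.0)

    def test_hundredfold_ratio(self):
        # ln(2.3e9 / 2.3e7) = ln(100), independently 2*ln(10)
        assert compute_target(2.3e9, 2.3e7) == pytest.approx(2 * math.log(10))

    @pytest.mark.parametrize("kq, kref", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_nonpositive_rates_rejected(self, kq, kref):
        with pytest.raises(ValueError):
            compute_target(kq, kref)

    def test_soac_of_reference_is_zero(self):
        assert target_from_soac(1.0) == 0.0

    def test_soac_consistent_with_rate_ratio(self):
        kq, kref = 5.4e8, 2.3e7
        assert target_from_soac(kq / kref) == pytest.approx(
            compute_target(kq, kref), abs=1e-12)

    def test_nonpositive_soac_rejected(self):
        with pytest.raises(ValueError):
            target_from_soac(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k1=st.floats(1e3, 1e12), k2=st.floats(1e3, 1e12),
           kref=st.floats(1e3, 1e12))
    def test_target_monotone_in_rates(self, k1, k2, kref):
        # strictly increasing in k_q, strictly decreasing in k_ref
        lo, hi = sorted((k1, k2))
        if lo < hi:
            assert compute_target(lo, kref) < compute_target(hi, kref)
            assert compute_target(kref, lo) > compute_target(kref, hi)


CSV_OK = """id,name,smiles,soac
c1,alpha-tocopherol,CC1=C(C(=C2CCC(OC2=C1C)(C)CCCC(C)CCCC(C)CCCC(C)C)C)O,1.0
c2,phenol,c1ccccc1O,0.03
c3,beta-carotene,CC1=C(C(CCC1)(C)C)/C=C/C(=C/C=C/C(=C/C=C/C=C(\\C)/C=C/C=C(\\C)/C=C/C2=C(CCCC2(C)C)C)/C)/C,55.0
"""


class TestReadCompounds:
    def test_happy_path(self, tmp_path):
        p = tmp_path / "compounds.csv"
        p.write_text(CSV_OK)
        records, rej = read_compounds(p)
        assert len(records) == 3 and len(rej) == 0
        assert records[0].y == 0.0
        assert records[2].y == pytest.approx(math.log(55.0))

    def test_bad_activity_row_is_rejected_not_fatal(self, tmp_path):
        p = tmp_path / "compounds.csv"
        p.write_text("id,name,smiles,soac\nc1,a,CCO,abc\nc2,b,CCN,2.0\n")
        records, rej = read_compounds(p)
        assert [r.id for r in records] == ["c2"]
        assert rej.rows[0][0] == "c1"

    def test_bad_smiles_row_is_rejected(self, tmp_path):
        p = tmp_path / "compounds.csv"
        p.write_text("id,name,smiles,soac\nc1,a,not_a_smiles(((,1.0\nc2,b,CCO,2.0\n")
        records, rej = read_compounds(p)
        assert [r.id for r in records] == ["c2"]
        assert "SMILES" in rej.rows[0][1]

    def test_soac_takes_precedence_over_rates(self, tmp_path):
        p = tmp_path / "compounds.csv"
        p.write_text("id,name,smiles,soac,k_q\nc1,a,CCO,2.0,9.9e9\n")
        records, _ = read_compounds(p, k_ref=2.3e7)
        assert records[0].y == pytest.approx(math.log(2.0))

    def test_rates_used_when_soac_absent(self, tmp_path):
        p = tmp_path / "compounds.csv"
        p.write_text("id,name,smiles,k_q\nc1,a,CCO,2.3e9\n")
        records, _ = read_compounds(p, k_ref=2.3e7)
        assert records[0].y == pytest.approx(math.log(100))

    def test_missing_columns_fail_fast(self, tmp_path):
        p = tmp_path / "compounds.csv"
        p.write_text("id,name,soac\nc1,a,1.0\n")
        with pytest.raises(SchemaError, match="smiles"):
            read_compounds(p)
        p.write_text("id,name,smiles\nc1,a,CCO\n")
        with pytest.raises(SchemaError):
            read_compounds(p)

    def test_kq_without_reference_constant(self, tmp_path):
        p = tmp_path / "compounds.csv"
        p.write_text("id,name,smiles,k_q\nc1,a,CCO,1e8\n")
        with pytest.raises(SchemaError, match="reference"):
            read_compounds(p)


def _record(smiles="CCO", rid="r1"):
    return make_record(rid, "x", smiles, soac=1.0)


class TestDescriptorBackends:
    def test_stub_is_deterministic(self):
        b = StubDescriptorBackend()
        d1 = compute_descriptors(_record(), b)
        d2 = compute_descriptors(_record(), b)
        assert d1 == d2

    def test_stub_gap_invariant(self):
        d = compute_descriptors(_record(), StubDescriptorBackend())
        assert d.gap == pytest.approx(d.lumo - d.homo, abs=1e-9)
        assert all(math.isfinite(v) for v in d.descriptors_2d.values())

    def test_toolkit_invariant_under_atom_reordering(self):
        # canonicalization oracle: both spellings of ethanol canonicalize
        # to the same SMILES, hence identical descriptors
        assert canonical_smiles("CCO") == canonical_smiles("OCC")
        b = ToolkitDescriptorBackend()
        d1 = compute_descriptors(_record("CCO"), b)
        d2 = compute_descriptors(_record("OCC"), b)
        assert d1 == d2

    def test_toolkit_2d_values_match_rdkit_directly(self):
        from rdkit.Chem import Descriptors
        b = ToolkitDescriptorBackend(descriptor_names=("MolWt", "BalabanJ"))
        d = compute_descriptors(_record("c1ccccc1O"), b)
        mol = Chem.MolFromSmiles("c1ccccc1O")
        assert d.descriptors_2d["MolWt"] == pytest.approx(Descriptors.MolWt(mol))
        assert d.descriptors_2d["BalabanJ"] == pytest.approx(Descriptors.BalabanJ(mol))

    def test_stub_distinguishes_molecules(self):
        b = StubDescriptorBackend()
        assert compute_descriptors(_record("CCO"), b) != \
            compute_descriptors(_record("CCN"), b)


SYNTHETIC_LISTING = """\
 -- synthetic engine listing for parser tests (not real output) --
          FINAL HEAT OF FORMATION =        -57.79970 KCAL/MOL

          HOMO LUMO ENERGIES (EV) =         -9.452  1.234

 DIPOLE           X         Y         Z       TOTAL
 POINT-CHG.     0.571     1.648     0.000     1.744
 HYBRID         0.090     0.252     0.000     0.268
 SUM            0.661     1.900     0.000     2.012
"""


def test_quantum_listing_parser():
    parsed = parse_quantum_listing(SYNTHETIC_LISTING)
    assert parsed == {"homo": -9.452, "lumo": 1.234,
                      "heat_of_formation": -57.7997, "dipole": 2.012}
    with pytest.raises(FeaturizationError, match="missing"):
        parse_quantum_listing("nothing useful here")


class TestFingerprints:
    def test_deterministic_and_binary(self):
        fp1 = compute_fingerprint(_record("c1ccccc1O"), radius=2, n_bits=512)
        fp2 = compute_fingerprint(_record("c1ccccc1O"), radius=2, n_bits=512)
        assert np.array_equal(fp1, fp2)
        assert set(np.unique(fp1)) <= {0.0, 1.0}

    def test_nonempty_molecule_sets_a_bit(self):
        assert compute_fingerprint(_record("C"), n_bits=64).sum() >= 1

    def test_radius_zero_environments_subset_of_radius_two(self):
        # for methane the radius-0 atom environments are among those hashed
        # at radius 2, so its on-bit set is a subset
        rec = _record("C")
        bits0 = set(np.flatnonzero(compute_fingerprint(rec, radius=0, n_bits=2048)))
        bits2 = set(np.flatnonzero(compute_fingerprint(rec, radius=2, n_bits=2048)))
        assert bits0 <= bits2

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            compute_fingerprint(_record(), n_bits=0)
        with pytest.raises(ValueError):
            compute_fingerprint(_record(), radius=-1)


class _FailOn(StubDescriptorBackend):
    def __init__(self, bad_smiles):
        super().__init__()
        self.bad = canonical_smiles(bad_smiles)

    def compute(self, smiles):
        if canonical_smiles(smiles) == self.bad:
            raise FeaturizationError("synthetic backend failure")
        return super().compute(smiles)


class TestBuildFeatureTables:
    SMILES = ["CCO", "CCN", "c1ccccc1", "c1ccccc1O", "CC(C)=O"]

    def records(self):
        return [make_record(f"c{i}", "x", s, soac=float(i + 1))
                for i, s in enumerate(self.SMILES)]

    def test_aligned_tables(self):
        t = build_feature_tables(self.records(), StubDescriptorBackend(),
                                 radius=2, n_bits=128)
        assert t.descriptors.sample_ids == t.fingerprints.sample_ids
        assert t.descriptors.n_samples == 5
        assert list(t.targets.index) == t.descriptors.sample_ids
        assert t.fingerprints.n_features == 128

    def test_failing_compound_dropped_from_both(self):
        t = build_feature_tables(self.records(), _FailOn("c1ccccc1"),
                                 radius=2, n_bits=64)
        assert t.descriptors.n_samples == 4
        assert t.fingerprints.n_samples == 4
        assert "c2" not in t.descriptors.sample_ids
        assert t.rejections.rows[0][0] == "c2"

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_feature_tables(self.records()[:2], StubDescriptorBackend())

    def test_featurization_repeatable(self):
        b = StubDescriptorBackend()
        t1 = build_feature_tables(self.records(), b, n_bits=64)
        t2 = build_feature_tables(self.records(), b, n_bits=64)
        assert t1.descriptors.values.equals(t2.descriptors.values)
        assert t1.fingerprints.values.equals(t2.fingerprints.values)


def test_compound_record_requires_activity():
    with pytest.raises(FeaturizationError):
        CompoundRecord(id="x", name="x", smiles="CCO", y=0.0)
    with pytest.raises(FeaturizationError, match="reference"):
        make_record("x", "x", "CCO", k_q=1e8)
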