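"""Compound ingestion and featurization.

Turns a compound table (isomeric SMILES plus singlet-oxygen rate data)
into the two explanatory-variable sets used throughout the study:

* **molecular descriptors** — quantum descriptors (HOMO, LUMO, HOMO-LUMO
  gap, heat of formation, dipole moment) plus 2-D topological/constitutional
  descriptors, and
* **Morgan fingerprint bits** — hashed circular substructure flags,

together with the objective variable ``y = ln(k_q / k_ref)``, the natural
logarithm of the quenching-rate ratio against alpha-tocopherol (for
compounds reported directly as a SOAC ratio, ``y = ln(SOAC)``).

Descriptor computation sits behind a backend contract with three
interchangeable implementations:

``stub``
    Deterministic pseudo-descriptors hashed from the canonical SMILES.
    No external engine; identical schema to the toolkit backend.  This is
    the backend the test suite runs on.
``toolkit``
    RDKit 2-D descriptors; quantum fields are delegated to a quantum
    sub-backend (the stub one unless a semiempirical engine is attached).
``quantum``
    RDKit 2-D descriptors plus a subprocess adapter around an external
    semiempirical engine (MOPAC/PM7) for HOMO/LUMO/heat-of-formation/
    dipole.  Raises a :class:`~soacml.errors.CapabilityError` when the
    executable is absent — never silent zeros.
"""

from __future__ import annotations

import hashlib
import math
import re
import shutil
import subprocess
import tempfile
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, rdFingerprintGenerator

from .errors import CapabilityError, FeaturizationError, SchemaError
from .table import DESCRIPTOR, FINGERPRINT_BIT, FeatureTable

RDLogger.DisableLog("rdApp.*")

QUANTUM_FIELDS = ("homo", "lumo", "gap", "heat_of_formation", "dipole")

#: default 2-D descriptor list: every RDKit 2-D descriptor (the study
#: started from "more than 100" RDKit + PM7 descriptors; the exact list is
#: a package default, recorded in every run's metadata).
DEFAULT_2D_DESCRIPTORS: tuple[str, ...] = tuple(name for name, _ in Descriptors.descList)


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

def compute_target(k_q: float, k_ref: float) -> float:
    """``y = ln(k_q / k_ref)``: log quenching-rate ratio vs. the reference.

    The reference compound (alpha-tocopherol, ``k_q == k_ref``) maps to 0.
    """
    if not (k_q > 0):
        raise ValueError(f"quenching rate constant must be > 0, got {k_q}")
    if not (k_ref > 0):
        raise ValueError(f"reference rate constant must be > 0, got {k_ref}")
    return math.log(k_q / k_ref)


def target_from_soac(soac: float) -> float:
    """``y = ln(SOAC)`` — consistent with :func:`compute_target` since the
    SOAC value is by definition the rate ratio ``k_q / k_ref``."""
    if not (soac > 0):
        raise ValueError(f"SOAC value must be > 0, got {soac}")
    return math.log(soac)


# ---------------------------------------------------------------------------
# compound records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: identifiers, isomeric SMILES, rate data and target."""

    id: str
    name: str
    smiles: str
    k_q: Optional[float] = None
    soac: Optional[float] = None
    y: float = field(default=math.nan)

    def __post_init__(self):
        if self.k_q is None and self.soac is None:
            raise FeaturizationError(
                f"compound {self.id!r}: needs a SOAC value or a rate constant")
        if not math.isfinite(self.y):
            raise FeaturizationError(f"compound {self.id!r}: target y is not finite")


def make_record(id: str, name: str, smiles: str, *,
                soac: Optional[float] = None,
                k_q: Optional[float] = None,
                k_ref: Optional[float] = None) -> CompoundRecord:
    """Build a record, deriving ``y``. SOAC takes precedence over rates."""
    if soac is not None:
        y = target_from_soac(soac)
    elif k_q is not None:
        if k_ref is None:
            raise FeaturizationError(
                f"compound {id!r}: k_q given but no reference rate constant configured")
        y = compute_target(k_q, k_ref)
    else:
        raise FeaturizationError(f"compound {id!r}: needs soac or k_q")
    return CompoundRecord(id=str(id), name=str(name), smiles=str(smiles),
                          k_q=k_q, soac=soac, y=y)


@dataclass
class RejectionReport:
    """Per-row featurization/ingestion failures; the run continues."""

    rows: list[tuple[str, str]] = field(default_factory=list)  # (row id, reason)

    def add(self, row_id: str, reason: str) -> None:
        self.rows.append((str(row_id), reason))

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["id", "reason"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _parse_positive(raw, what: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise FeaturizationError(f"{what} value {raw!r} is not a number")
    if not math.isfinite(value):
        raise FeaturizationError(f"{what} value {raw!r} is not finite")
    return value


def read_compounds(path, *, k_ref: Optional[float] = None,
                   sep: str = ",") -> tuple[list[CompoundRecord], RejectionReport]:
    """Read a delimited compound table into records, deriving targets.

    Required columns: ``id``, ``smiles`` and at least one of ``soac`` /
    ``k_q`` (the latter needs ``k_ref``).  Malformed rows (bad SMILES,
    non-numeric or non-positive activity) are collected into the rejection
    report and the run continues.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "smiles"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"compound table missing required columns: {missing}")
    has_soac = "soac" in df.columns
    has_kq = "k_q" in df.columns
    if not has_soac and not has_kq:
        raise SchemaError("compound table needs a 'soac' or 'k_q' column")
    if has_kq and not has_soac and k_ref is None:
        raise SchemaError("'k_q' column present but no reference rate constant given")

    records: list[CompoundRecord] = []
    rejections = RejectionReport()
    for _, row in df.iterrows():
        rid = row["id"]
        try:
            smiles = row["smiles"]
            if not isinstance(smiles, str) or Chem.MolFromSmiles(smiles) is None:
                raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
            soac = _parse_positive(row["soac"], "soac") if has_soac else None
            k_q = _parse_positive(row["k_q"], "k_q") if has_kq else None
            records.append(make_record(
                rid, row.get("name", "") or "", smiles,
                soac=soac, k_q=k_q, k_ref=k_ref))
        except (FeaturizationError, ValueError) as exc:
            rejections.add(rid, str(exc))
    return records, rejections


def targets_of(records: Sequence[CompoundRecord]) -> pd.Series:
    return pd.Series({r.id: r.y for r in records}, name="y")


# ---------------------------------------------------------------------------
# descriptor backends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorSet:
    """Quantum + 2-D descriptors for one compound (all values finite)."""

    homo: float                 # eV
    lumo: float                 # eV
    gap: float                  # eV, lumo - homo
    heat_of_formation: float    # kcal/mol
    dipole: float               # Debye
    descriptors_2d: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        scalars = [self.homo, self.lumo, self.gap, self.heat_of_formation, self.dipole]
        if not all(math.isfinite(v) for v in scalars):
            raise FeaturizationError("non-finite quantum descriptor value")
        if abs(self.gap - (self.lumo - self.homo)) > 1e-9:
            raise FeaturizationError("gap must equal lumo - homo")
        bad = [k for k, v in self.descriptors_2d.items() if not math.isfinite(v)]
        if bad:
            raise FeaturizationError(f"non-finite 2-D descriptors: {bad[:5]}")

    def as_series(self) -> pd.Series:
        data = {"homo": self.homo, "lumo": self.lumo, "gap": self.gap,
                "heat_of_formation": self.heat_of_formation, "dipole": self.dipole}
        data.update(self.descriptors_2d)
        return pd.Series(data, dtype=float)


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


class QuantumBackend(ABC):
    """Supplies HOMO/LUMO (eV), heat of formation (kcal/mol), dipole (D)."""

    name: str = "abstract"

    @abstractmethod
    def compute(self, smiles: str) -> tuple[float, float, float, float]:
        """Return (homo, lumo, heat_of_formation, dipole)."""


class StubQuantumBackend(QuantumBackend):
    """Pseudo quantum descriptors hashed from the canonical SMILES.

    Values land in chemically plausible ranges (HOMO in [-10, -5] eV,
    LUMO above it, etc.) but carry no chemistry: the point is a cheap,
    fully deterministic stand-in with the real backends' schema.
    """

    name = "stub"

    def compute(self, smiles: str) -> tuple[float, float, float, float]:
        rng = _smiles_rng(smiles, salt="quantum")
        homo = -10.0 + 5.0 * rng.random()
        lumo = homo + 0.5 + 7.0 * rng.random()
        hof = -150.0 + 300.0 * rng.random()
        dipole = 10.0 * rng.random()
        return homo, lumo, hof, dipole


def _smiles_rng(smiles: str, salt: str) -> np.random.Generator:
    digest = hashlib.blake2b(f"{salt}|{canonical_smiles(smiles)}".encode(),
                             digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


class MopacQuantumBackend(QuantumBackend):
    """Subprocess adapter around a semiempirical engine (MOPAC, PM7).

    Embeds a 3-D conformer (ETKDG + MMFF), writes the engine's input deck,
    runs the executable, and parses HOMO/LUMO, heat of formation and the
    dipole moment from the output listing.
    """

    name = "mopac"

    def __init__(self, executable: str = "mopac", keywords: str = "PM7 PRECISE"):
        self.executable = executable
        self.keywords = keywords

    def compute(self, smiles: str) -> tuple[float, float, float, float]:
        exe = shutil.which(self.executable)
        if exe is None:
            raise CapabilityError(
                "mopac", f"executable {self.executable!r} not found on PATH")
        mol = Chem.AddHs(Chem.MolFromSmiles(canonical_smiles(smiles)))
        if AllChem.EmbedMolecule(mol, randomSeed=0xF00D) != 0:
            raise FeaturizationError(f"3-D embedding failed for {smiles!r}")
        AllChem.MMFFOptimizeMolecule(mol)
        deck = self.write_input_deck(mol)
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "job.mop"
            inp.write_text(deck)
            subprocess.run([exe, str(inp)], check=True, capture_output=True)
            out = inp.with_suffix(".out")
            if not out.exists():
                raise CapabilityError("mopac", "engine produced no output listing")
            parsed = parse_quantum_listing(out.read_text())
        return (parsed["homo"], parsed["lumo"],
                parsed["heat_of_formation"], parsed["dipole"])

    def write_input_deck(self, mol: Chem.Mol) -> str:
        conf = mol.GetConformer()
        lines = [self.keywords, "generated by soacml", ""]
        for atom in mol.GetAtoms():
            p = conf.GetAtomPosition(atom.GetIdx())
            lines.append(f"{atom.GetSymbol():2s} {p.x:12.6f} 1 {p.y:12.6f} 1 {p.z:12.6f} 1")
        return "\n".join(lines) + "\n"


_HOMO_LUMO_RE = re.compile(
    r"HOMO\s+LUMO\s+ENERGIES\s*\(EV\)\s*=?\s*(-?\d+\.\d+)\s+(-?\d+\.\d+)")
_HOF_RE = re.compile(r"FINAL\s+HEAT\s+OF\s+FORMATION\s*=\s*(-?\d+\.\d+)\s*KCAL")
_DIPOLE_SUM_RE = re.compile(r"^\s*SUM\s+(?:-?\d+\.\d+\s+){3}(-?\d+\.\d+)\s*$",
                            re.MULTILINE)


def parse_quantum_listing(text: str) -> dict[str, float]:
    """Extract HOMO/LUMO/heat-of-formation/dipole from an engine listing."""
    hl = _HOMO_LUMO_RE.search(text)
    hof = _HOF_RE.search(text)
    dip = _DIPOLE_SUM_RE.search(text)
    missing = [label for label, m in
               (("HOMO/LUMO", hl), ("heat of formation", hof), ("dipole", dip))
               if m is None]
    if missing:
        raise FeaturizationError(f"engine listing missing: {missing}")
    return {"homo": float(hl.group(1)), "lumo": float(hl.group(2)),
            "heat_of_formation": float(hof.group(1)), "dipole": float(dip.group(1))}


class DescriptorBackend(ABC):
    """Contract: canonical SMILES in, complete DescriptorSet out."""

    name: str = "abstract"

    @abstractmethod
    def compute(self, smiles: str) -> DescriptorSet:
        ...


class StubDescriptorBackend(DescriptorBackend):
    """Fully deterministic pseudo-descriptors from the canonical SMILES.

    Shares the toolkit backend's 2-D descriptor schema so the two are
    interchangeable downstream.
    """

    name = "stub"

    def __init__(self, descriptor_names: Sequence[str] = DEFAULT_2D_DESCRIPTORS):
        self.descriptor_names = tuple(descriptor_names)
        self._quantum = StubQuantumBackend()

    def compute(self, smiles: str) -> DescriptorSet:
        homo, lumo, hof, dipole = self._quantum.compute(smiles)
        rng = _smiles_rng(smiles, salt="2d")
        values = rng.normal(0.0, 1.0, size=len(self.descriptor_names))
        d2 = dict(zip(self.descriptor_names, values.tolist()))
        return DescriptorSet(homo=homo, lumo=lumo, gap=lumo - homo,
                             heat_of_formation=hof, dipole=dipole,
                             descriptors_2d=d2)


class ToolkitDescriptorBackend(DescriptorBackend):
    """RDKit 2-D descriptors; quantum fields from a pluggable sub-backend.

    With no semiempirical engine attached the quantum fields come from the
    deterministic stub (recorded in the backend name); attach
    :class:`MopacQuantumBackend` for real PM7 values.
    """

    name = "toolkit"

    def __init__(self, descriptor_names: Sequence[str] = DEFAULT_2D_DESCRIPTORS,
                 quantum: QuantumBackend | None = None):
        self.descriptor_names = tuple(descriptor_names)
        self.quantum = quantum or StubQuantumBackend()
        self.name = f"toolkit+{self.quantum.name}"
        self._funcs = dict(Descriptors.descList)
        unknown = [n for n in self.descriptor_names if n not in self._funcs]
        if unknown:
            raise CapabilityError("toolkit", f"unknown 2-D descriptors: {unknown[:5]}")

    def compute(self, smiles: str) -> DescriptorSet:
        mol = Chem.MolFromSmiles(canonical_smiles(smiles))
        d2 = {}
        for name in self.descriptor_names:
            try:
                d2[name] = float(self._funcs[name](mol))
            except Exception as exc:
                raise FeaturizationError(f"descriptor {name} failed: {exc}") from exc
        homo, lumo, hof, dipole = self.quantum.compute(smiles)
        return DescriptorSet(homo=homo, lumo=lumo, gap=lumo - homo,
                             heat_of_formation=hof, dipole=dipole,
                             descriptors_2d=d2)


def get_backend(name: str) -> DescriptorBackend:
    """Backend registry: ``stub``, ``toolkit`` or ``quantum``."""
    if name == "stub":
        return StubDescriptorBackend()
    if name == "toolkit":
        return ToolkitDescriptorBackend()
    if name == "quantum":
        return ToolkitDescriptorBackend(quantum=MopacQuantumBackend())
    raise CapabilityError(name, "supported backends: stub, toolkit, quantum")


# ---------------------------------------------------------------------------
# featurization operations
# ---------------------------------------------------------------------------

def compute_descriptors(record: CompoundRecord,
                        backend: DescriptorBackend) -> DescriptorSet:
    """Full descriptor set for one compound via the given backend."""
    return backend.compute(record.smiles)


def compute_fingerprint(record: CompoundRecord, radius: int = 2,
                        n_bits: int = 2048) -> np.ndarray:
    """Hashed Morgan (circular) fingerprint as a 0/1 vector.

    Radius 2 flags every atom-centred environment up to two bonds out —
    the substructure resolution the importance analysis interprets.
    """
    if n_bits < 1:
        raise ValueError(f"n_bits must be >= 1, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {record.smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(float)


class FeatureTables(NamedTuple):
    descriptors: FeatureTable
    fingerprints: FeatureTable
    targets: pd.Series
    rejections: RejectionReport


def build_feature_tables(records: Sequence[CompoundRecord],
                         backend: DescriptorBackend,
                         radius: int = 2, n_bits: int = 2048) -> FeatureTables:
    """Featurize all compounds into aligned descriptor/fingerprint tables.

    A compound failing either featurizer is dropped from *both* tables
    (and from the target vector) and logged in the rejection report —
    small-n regression cannot tolerate silent imputation.
    """
    if len(records) < 3:
        raise ValueError(f"need at least 3 compounds, got {len(records)}")
    desc_rows, fp_rows, kept = {}, {}, []
    rejections = RejectionReport()
    for rec in records:
        try:
            desc_rows[rec.id] = compute_descriptors(rec, backend).as_series()
            fp_rows[rec.id] = compute_fingerprint(rec, radius=radius, n_bits=n_bits)
        except (FeaturizationError, ValueError) as exc:
            desc_rows.pop(rec.id, None)
            rejections.add(rec.id, str(exc))
            continue
        kept.append(rec)
    if not kept:
        raise FeaturizationError("every compound failed featurization")

    desc_df = pd.DataFrame({rec.id: desc_rows[rec.id] for rec in kept}).T
    fp_names = [f"fp_{i + 1:04d}" for i in range(n_bits)]
    fp_df = pd.DataFrame(np.vstack([fp_rows[rec.id] for rec in kept]),
                         index=[rec.id for rec in kept], columns=fp_names)
    desc_table = FeatureTable(desc_df, {c: DESCRIPTOR for c in desc_df.columns})
    fp_table = FeatureTable(fp_df, {c: FINGERPRINT_BIT for c in fp_names})
    y = pd.Series({rec.id: rec.y for rec in kept}, name="y")
    return FeatureTables(desc_table, fp_table, y, rejections)
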