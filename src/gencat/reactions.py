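"""Reaction records and selectivity unit conversions.

One record describes an asymmetric Pictet-Spengler condensation: a tryptamine
derivative (SubA) and a carbonyl compound (SubB) cyclizing to a
tetrahydro-beta-carboline under a chiral organocatalyst, optionally with an
acid or acyl-halide co-catalyst.  Enantioselectivity may be given as an
enantiomeric ratio (er, major:minor), an enantiomeric excess (ee, fraction)
or a free-energy difference between the diastereomeric transition states
(ddg, kcal/mol); the three encodings are interconverted via

    er = exp(ddg / RT),    ee = (er - 1) / (er + 1).

ddg is stored as a non-negative magnitude so that er >= 1 always holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .constants import R_KCAL, T_DEFAULT

_REL_TOL = 1e-6  # consistency tolerance for redundant user-supplied fields

REACTION_COLUMNS = [
    "sub_a", "sub_b", "catalyst", "cocatalyst", "solvent", "temperature_K",
    "er", "ee", "ddg_kcal", "descriptor_kcal", "source",
]

# quinuclidine core, the bifunctional HBD+HBA motif of cinchona alkaloids
_CINCHONA_QUERY = Chem.MolFromSmarts("C1CC2CCN1CC2")


def ddg_from_er(er: float, temperature: float = T_DEFAULT) -> float:
    """Activation free-energy difference RT*ln(er) in kcal/mol (er >= 1)."""
    if er < 1.0:
        raise ValueError(
            f"er = {er} < 1; pass the major:minor magnitude (invert the ratio)"
        )
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature * math.log(er)


def er_from_ddg(ddg: float, temperature: float = T_DEFAULT) -> float:
    """Enantiomeric ratio exp(ddg/RT); inverse of :func:`ddg_from_er`."""
    if ddg < 0:
        raise ValueError(f"ddg = {ddg} < 0; supply the magnitude")
    return math.exp(ddg / (R_KCAL * temperature))


def ee_from_er(er: float) -> float:
    """Enantiomeric excess as a fraction in [0, 1)."""
    if er < 1.0:
        raise ValueError(f"er = {er} < 1; invert the ratio")
    return (er - 1.0) / (er + 1.0)


def er_from_ee(ee: float) -> float:
    if not 0.0 <= ee < 1.0:
        raise ValueError(f"ee = {ee} outside [0, 1)")
    return (1.0 + ee) / (1.0 - ee)


def ee_from_ddg(ddg: float, temperature: float = T_DEFAULT) -> float:
    """ee in percent from ddg; equals 100*tanh(ddg/(2RT))."""
    if ddg < 0:
        raise ValueError(f"ddg = {ddg} < 0; supply the magnitude")
    return 100.0 * math.tanh(ddg / (2.0 * R_KCAL * temperature))


def ddg_from_ee(ee: float, temperature: float = T_DEFAULT) -> float:
    return ddg_from_er(er_from_ee(ee), temperature)


def is_cinchona(catalyst_smiles: str) -> bool:
    """Whether the catalyst carries a quinuclidine (cinchona alkaloid) core.

    Cinchona-type bifunctional HBD+HBA catalysts operate by a different
    mechanism and are excluded from descriptor-model training.
    """
    mol = Chem.MolFromSmiles(catalyst_smiles)
    return mol is not None and mol.HasSubstructMatch(_CINCHONA_QUERY)


@dataclass(frozen=True)
class ReactionRecord:
    """One Pictet-Spengler reaction with selectivity in all three encodings."""

    sub_a: str
    sub_b: str
    catalyst: str
    cocatalyst: str | None = None
    solvent: str = ""
    temperature: float = T_DEFAULT
    er: float | None = None
    ee: float | None = None          # fraction in [0, 1)
    ddg: float | None = None         # kcal/mol, magnitude
    descriptor: float | None = None  # relative energy of intermediate 2, kcal/mol
    source: str = "synthetic"

    def completed(self) -> "ReactionRecord":
        """Fill the missing selectivity encodings from whichever is present,
        and verify consistency of any redundant ones."""
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        er, ee, ddg = self.er, self.ee, self.ddg
        if er is None and ee is None and ddg is None:
            return self
        if er is None:
            er = er_from_ee(ee) if ee is not None else er_from_ddg(ddg, self.temperature)
        for name, given, implied in (
            ("ee", ee, ee_from_er(er)),
            ("ddg", ddg, ddg_from_er(er, self.temperature)),
        ):
            if given is not None and not math.isclose(
                given, implied, rel_tol=_REL_TOL, abs_tol=_REL_TOL
            ):
                raise ValueError(
                    f"inconsistent selectivity: {name}={given} but er={er} "
                    f"implies {name}={implied:.6g}"
                )
        return replace(
            self,
            er=er,
            ee=ee_from_er(er),
            ddg=ddg_from_er(er, self.temperature),
        )

    def validate_smiles(self) -> None:
        for component in ("sub_a", "sub_b", "catalyst", "cocatalyst"):
            smi = getattr(self, component)
            if component == "cocatalyst" and not smi:
                continue
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"{component}: unparseable SMILES {smi!r}")


@dataclass(frozen=True)
class SubstratePanel:
    """An ordered set of (SubA, SubB) pairs on which candidates are scored.

    The generality probing set (GPS) is such a panel, chosen by farthest
    point sampling to cover the substrate chemical space.
    """

    pairs: tuple[tuple[str, str], ...]
    name: str = "panel"
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("substrate panel must be non-empty")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("substrate panel contains duplicate pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["sub_a", "sub_b"])

    @classmethod
    def from_csv(cls, path, name: str = "panel") -> "SubstratePanel":
        df = pd.read_csv(path)
        return cls(tuple(zip(df["sub_a"], df["sub_b"])), name=name)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_reaction_table(path) -> list[ReactionRecord]:
    """Read ``reactions.csv``, completing and validating every row."""
    df = pd.read_csv(path)
    records = []
    for i, row in df.iterrows():
        def _get(col, default=None):
            v = row.get(col)
            return default if v is None or (isinstance(v, float) and math.isnan(v)) else v

        try:
            rec = ReactionRecord(
                sub_a=str(row["sub_a"]),
                sub_b=str(row["sub_b"]),
                catalyst=str(row["catalyst"]),
                cocatalyst=_get("cocatalyst") or None,
                solvent=str(_get("solvent", "")),
                temperature=float(_get("temperature_K", T_DEFAULT)),
                er=_get("er"),
                ee=_get("ee"),
                ddg=_get("ddg_kcal"),
                descriptor=_get("descriptor_kcal"),
                source=str(_get("source", "literature")),
            ).completed()
            rec.validate_smiles()
        except (ValueError, KeyError) as exc:
            raise ValueError(f"reactions row {i}: {exc}") from None
        records.append(rec)
    return records


def to_frame(records: Iterable[ReactionRecord]) -> pd.DataFrame:
    rows = [
        {
            "sub_a": r.sub_a,
            "sub_b": r.sub_b,
            "catalyst": r.catalyst,
            "cocatalyst": r.cocatalyst or "",
            "solvent": r.solvent,
            "temperature_K": r.temperature,
            "er": r.er,
            "ee": r.ee,
            "ddg_kcal": r.ddg,
            "descriptor_kcal": r.descriptor,
            "source": r.source,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=REACTION_COLUMNS)


def write_reaction_table(records: Iterable[ReactionRecord], path) -> None:
    to_frame(records).to_csv(path, index=False)


def unique_transformations(records: Sequence[ReactionRecord]) -> int:
    """Number of distinct (SubA, SubB) pairs, i.e. distinct products,
    comparing canonical SMILES."""
    seen = set()
    for r in records:
        seen.add((_canon(r.sub_a), _canon(r.sub_b)))
    return len(seen)


def _canon(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else smiles
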