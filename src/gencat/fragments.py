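"""Fragment library, catalyst templates and combinatorial SMILES assembly.

Catalyst candidates are chromosomes over a library of scaffold templates and
substituent fragments.  A template is a "flexible" SMILES string carrying
named placeholder tokens such as ``{R1a}``; assembly is literal substitution
of each token by a fragment's SMILES followed by RDKit canonicalization.
Fragments are grouped into four substitution categories (R1-R4) that control
which slots they may occupy.  Symmetric slot groups (e.g. the 6/6' positions
of a BINOL/SPINOL phosphoric-acid scaffold) are constrained to receive the
same fragment, which keeps candidates synthetically sensible and shrinks the
combinatorial space accordingly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

CATEGORIES = ("R1", "R2", "R3", "R4")

_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z0-9_]+)\}")


class LibraryError(ValueError):
    """Raised for malformed fragments, templates or libraries."""


class AssemblyError(ValueError):
    """Raised when a chromosome cannot be assembled into a valid molecule."""


def canonical_smiles(smiles: str) -> str:
    """Canonical RDKit SMILES, or raise ``ValueError`` on a parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Fragment:
    """A monovalent substituent with an implicit single attachment point.

    ``smiles`` is the splice text substituted for a placeholder token; it must
    yield a valid molecule when grafted onto a carbon probe.  Ring-closure
    digits inside fragments should avoid those of the host scaffold (the
    packaged libraries use 8/9).
    """

    id: str
    smiles: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LibraryError(
                f"fragment {self.id!r}: unknown category {self.category!r} "
                f"(expected one of {CATEGORIES})"
            )
        # Grafting onto a methyl probe checks both parseability and that the
        # fragment presents exactly one attachment point to its host.
        if Chem.MolFromSmiles(f"C{self.smiles}") is None:
            raise LibraryError(
                f"fragment {self.id!r}: SMILES {self.smiles!r} does not "
                "splice to a valid molecule"
            )


@dataclass(frozen=True)
class CatalystTemplate:
    """A catalyst scaffold with named, category-typed substitution slots."""

    id: str
    family: str
    scaffold: str
    slots: tuple[tuple[str, str], ...]  # (slot name, fragment category)
    symmetric_groups: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        tokens = _PLACEHOLDER_RE.findall(self.scaffold)
        slot_names = [name for name, _ in self.slots]
        if len(set(slot_names)) != len(slot_names):
            raise LibraryError(f"template {self.id!r}: duplicate slot names")
        for name, category in self.slots:
            if category not in CATEGORIES:
                raise LibraryError(
                    f"template {self.id!r}: slot {name!r} has unknown "
                    f"category {category!r}"
                )
            if tokens.count(name) != 1:
                raise LibraryError(
                    f"template {self.id!r}: placeholder {{{name}}} occurs "
                    f"{tokens.count(name)} times in scaffold (expected 1)"
                )
        extra = set(tokens) - set(slot_names)
        if extra:
            raise LibraryError(
                f"template {self.id!r}: scaffold placeholders {sorted(extra)} "
                "are not declared as slots"
            )
        categories = dict(self.slots)
        for group in self.symmetric_groups:
            unknown = set(group) - set(slot_names)
            if unknown:
                raise LibraryError(
                    f"template {self.id!r}: symmetric group references "
                    f"unknown slots {sorted(unknown)}"
                )
            if len({categories[s] for s in group}) != 1:
                raise LibraryError(
                    f"template {self.id!r}: symmetric group {group} mixes "
                    "fragment categories"
                )

    @property
    def slot_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.slots)

    def slot_category(self, slot: str) -> str:
        return dict(self.slots)[slot]

    def independent_groups(self) -> list[tuple[tuple[str, ...], str]]:
        """Slot groups that carry independent genes: each symmetric group is
        one gene, every remaining slot its own.  Returns (slots, category)."""
        grouped: set[str] = set()
        out: list[tuple[tuple[str, ...], str]] = []
        for group in self.symmetric_groups:
            out.append((tuple(group), self.slot_category(group[0])))
            grouped.update(group)
        for name, category in self.slots:
            if name not in grouped:
                out.append(((name,), category))
        # deterministic gene order: by first slot's position in the template
        order = {name: i for i, (name, _) in enumerate(self.slots)}
        out.sort(key=lambda g: order[g[0][0]])
        return out


@dataclass(frozen=True)
class CatalystCandidate:
    """A template plus a slot -> fragment assignment (the GA chromosome)."""

    template_id: str
    assignment: tuple[tuple[str, str], ...]  # (slot name, fragment id), slot order
    assembled_smiles: str

    @property
    def assignment_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    def key(self) -> tuple:
        """Hashable identity of the chromosome."""
        return (self.template_id, self.assignment)


@dataclass
class FragmentLibrary:
    """Templates plus fragments, indexed for assembly and sampling."""

    templates: list[CatalystTemplate]
    fragments: list[Fragment]
    _by_category: dict[str, list[Fragment]] = field(init=False, repr=False)
    _frag_by_id: dict[str, Fragment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        tids = [t.id for t in self.templates]
        fids = [f.id for f in self.fragments]
        for label, ids in (("template", tids), ("fragment", fids)):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise LibraryError(f"duplicate {label} ids: {sorted(dupes)}")
        self._by_category = {c: [] for c in CATEGORIES}
        for f in self.fragments:
            self._by_category[f.category].append(f)
        self._frag_by_id = {f.id: f for f in self.fragments}

    def fragment(self, frag_id: str) -> Fragment:
        try:
            return self._frag_by_id[frag_id]
        except KeyError:
            raise LibraryError(f"unknown fragment id {frag_id!r}") from None

    def template(self, template_id: str) -> CatalystTemplate:
        for t in self.templates:
            if t.id == template_id:
                return t
        raise LibraryError(f"unknown template id {template_id!r}")

    def category(self, name: str) -> list[Fragment]:
        return self._by_category[name]


def load_library(templates_file, fragments_file) -> FragmentLibrary:
    """Read ``templates.csv`` and ``fragments.csv`` into a validated library.

    fragments.csv columns: ``id,smiles,category``.  templates.csv columns:
    ``id,family,scaffold,slots,symmetric_groups`` where ``slots`` is a
    semicolon-separated list of ``slot:category`` and ``symmetric_groups``
    lists groups separated by ``;`` with members joined by ``|`` (may be
    empty).  Raises :class:`LibraryError` naming the offending row.
    """
    frag_df = pd.read_csv(fragments_file, dtype=str).fillna("")
    fragments = []
    for i, row in frag_df.iterrows():
        try:
            fragments.append(Fragment(row["id"], row["smiles"], row["category"]))
        except LibraryError as exc:
            raise LibraryError(f"fragments row {i}: {exc}") from None

    tmpl_df = pd.read_csv(templates_file, dtype=str).fillna("")
    templates = []
    for i, row in tmpl_df.iterrows():
        slots = tuple(
            tuple(part.split(":", 1))
            for part in row["slots"].split(";")
            if part.strip()
        )
        sym = tuple(
            tuple(g.split("|"))
            for g in str(row.get("symmetric_groups", "")).split(";")
            if g.strip()
        )
        try:
            templates.append(
                CatalystTemplate(row["id"], row["family"], row["scaffold"], slots, sym)
            )
        except LibraryError as exc:
            raise LibraryError(f"templates row {i}: {exc}") from None

    library = FragmentLibrary(templates, fragments)
    # spot-check: every template assembles with the first compatible fragment
    for t in templates:
        probe = {}
        for name, category in t.slots:
            pool = library.category(category)
            if not pool:
                continue
            probe[name] = pool[0].id
        if len(probe) == len(t.slots):
            for group in t.symmetric_groups:
                for s in group:
                    probe[s] = probe[group[0]]
            assemble(t, probe, library)
    return library


def assemble(
    template: CatalystTemplate,
    assignment: dict[str, str],
    library: FragmentLibrary,
) -> CatalystCandidate:
    """Substitute fragments into the scaffold and canonicalize the result."""
    missing = set(template.slot_names) - set(assignment)
    if missing:
        raise AssemblyError(
            f"template {template.id!r}: missing slots {sorted(missing)}"
        )
    for group in template.symmetric_groups:
        ids = {assignment[s] for s in group}
        if len(ids) != 1:
            raise AssemblyError(
                f"template {template.id!r}: symmetric slots {group} carry "
                f"different fragments {sorted(ids)}"
            )
    smiles = template.scaffold
    ordered = []
    for name, category in template.slots:
        frag = library.fragment(assignment[name])
        if frag.category != category:
            raise AssemblyError(
                f"template {template.id!r}: slot {name!r} expects category "
                f"{category}, fragment {frag.id!r} is {frag.category}"
            )
        smiles = smiles.replace("{" + name + "}", frag.smiles)
        ordered.append((name, frag.id))
    try:
        assembled = canonical_smiles(smiles)
    except ValueError as exc:
        raise AssemblyError(f"template {template.id!r}: {exc}") from None
    return CatalystCandidate(template.id, tuple(ordered), assembled)


def enumerate_count(library: FragmentLibrary) -> int:
    """Number of distinct chromosomes (assignments, not deduplicated SMILES).

    Product over each template's independent slot groups of the category
    size, summed over templates; symmetric groups contribute one factor.
    """
    total = 0
    for t in library.templates:
        n = 1
        for slots, category in t.independent_groups():
            size = len(library.category(category))
            if size == 0:
                raise LibraryError(
                    f"template {t.id!r}: slot group {slots} references empty "
                    f"category {category}"
                )
            n *= size
        total += n
    return total


def enumerate_candidates(library: FragmentLibrary):
    """Yield every candidate in the combinatorial space (small libraries)."""
    import itertools

    for t in library.templates:
        groups = t.independent_groups()
        pools = [library.category(cat) for _, cat in groups]
        for combo in itertools.product(*pools):
            assignment = {}
            for (slots, _), frag in zip(groups, combo):
                for s in slots:
                    assignment[s] = frag.id
            yield assemble(t, assignment, library)


def sample_random(
    library: FragmentLibrary, rng: np.random.Generator | int
) -> CatalystCandidate:
    """Draw a uniform template, then a uniform fragment per slot group."""
    if not library.templates:
        raise LibraryError("empty template library")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = library.templates[rng.integers(len(library.templates))]
    assignment = {}
    for slots, category in t.independent_groups():
        pool = library.category(category)
        if not pool:
            raise LibraryError(
                f"template {t.id!r}: empty fragment category {category}"
            )
        frag = pool[rng.integers(len(pool))]
        for s in slots:
            assignment[s] = frag.id
    return assemble(t, assignment, library)
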