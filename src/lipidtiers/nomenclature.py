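"""Lipid shorthand nomenclature: parsing, formatting, and acyl accounting.

Handles the sum-composition and molecular-species dialects used in targeted
lipidomics reports, e.g. ``TG 52:3`` (totals only), ``DG 36:3(18:2_18:1)``
(resolved acyls, sn-position unknown), ``PE O-38:6(O-18:2_20:4)`` (ether
linkage), ``SM 33:1;O2`` (sphingolipid with two extra oxygens), and
``Cer d18:1/17:0`` (sphingoid base / N-acyl, sn-resolved separator).

The parsed representation exposes, per species, the acyl-chain composition
and which chains are releasable by alkaline hydrolysis (saponifiable).
Sphingolipid N-acyls are amide-bound and resist hydrolysis, so they are
excluded from esterified-fatty-acid accounting; ether (O-) and vinyl-ether
(P-) chains are likewise not ester-bound.

Deliberately not covered: sterol/ganglioside acyl grammars, SMILES/InChI,
mass computation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional

__all__ = [
    "AcylChain",
    "SphingoidBase",
    "LipidClassDef",
    "LipidSpecies",
    "LipidNameError",
    "ClassRegistry",
    "default_registry",
    "parse_lipid_name",
    "format_lipid_name",
    "acyl_multiplicity",
]

ESTER = "ester"
ETHER = "ether"
VINYL_ETHER = "vinyl-ether"

_LINKAGE_PREFIX = {ETHER: "O-", VINYL_ETHER: "P-"}
_PREFIX_LINKAGE = {"O-": ETHER, "P-": VINYL_ETHER}


class LipidNameError(ValueError):
    """Raised on malformed, unknown-class, or inconsistent lipid names.

    ``position`` is the character offset in the original name where the
    problem was detected (or None if it concerns the name as a whole).
    """

    def __init__(self, message: str, name: str = "", position: Optional[int] = None):
        self.name = name
        self.position = position
        if position is not None:
            message = f"{message} (in {name!r} at position {position})"
        elif name:
            message = f"{message} (in {name!r})"
        super().__init__(message)


@dataclass(frozen=True)
class AcylChain:
    """A fatty-acyl chain: carbon count, double bonds, linkage, oxygenation.

    ``omega_class`` records the double-bond series ("n-3"/"n-6") only when
    declared by a panel (chromatographically resolved isomers); it is never
    inferred from carbons:double-bonds alone.
    """

    carbons: int
    double_bonds: int
    linkage: str = ESTER
    oxygenation: int = 0
    omega_class: Optional[str] = None

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.double_bonds >= self.carbons:
            raise ValueError(
                f"{self.double_bonds} double bonds impossible on {self.carbons} carbons"
            )
        if self.oxygenation < 0:
            raise ValueError("oxygenation must be >= 0")
        if self.linkage not in (ESTER, ETHER, VINYL_ETHER):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.omega_class not in (None, "n-3", "n-6", "n-7", "n-9"):
            raise ValueError(f"unknown omega class {self.omega_class!r}")

    @property
    def is_odd_chain(self) -> bool:
        return self.carbons % 2 == 1

    def shorthand(self) -> str:
        s = _LINKAGE_PREFIX.get(self.linkage, "") + f"{self.carbons}:{self.double_bonds}"
        if self.oxygenation == 1:
            s += ";O"
        elif self.oxygenation > 1:
            s += f";O{self.oxygenation}"
        return s


@dataclass(frozen=True)
class SphingoidBase:
    """Long-chain sphingoid backbone (e.g. d18:1): distinct from acyl chains.

    ``hydroxyls`` follows the d/t convention (d = di-, t = tri-hydroxy).
    Never matched by :func:`acyl_multiplicity`.
    """

    carbons: int
    double_bonds: int
    hydroxyls: int = 2

    def __post_init__(self):
        if self.carbons < 2 or self.double_bonds < 0 or self.double_bonds >= self.carbons:
            raise ValueError("invalid sphingoid base composition")
        if self.hydroxyls not in (2, 3):
            raise ValueError("sphingoid hydroxyls must be 2 (d) or 3 (t)")

    def shorthand(self) -> str:
        return f"{'d' if self.hydroxyls == 2 else 't'}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidClassDef:
    """One lipid class: how many chains attach and how many are ester-bound.

    ``saponifiable_slots`` < ``acyl_slots`` marks classes whose chains are
    not all released by alkaline hydrolysis: sphingolipid N-acyls (amide)
    and the free-acid class FA (nothing to hydrolyse).
    """

    code: str
    acyl_slots: int
    saponifiable_slots: int
    category: str

    def __post_init__(self):
        if not (0 <= self.saponifiable_slots <= self.acyl_slots):
            raise ValueError(
                f"class {self.code}: saponifiable_slots must lie in [0, acyl_slots]"
            )

    @property
    def has_sphingoid_base(self) -> bool:
        return self.category == "sphingolipid"


SUM_COMPOSITION = "sum-composition"
MOLECULAR_SPECIES = "molecular-species"


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid name.

    At molecular-species level ``acyls`` holds the resolved chains (plus the
    sphingoid base for sphingolipids); at sum-composition level it is empty
    and only the header totals are known.  ``separator`` preserves the
    dialect seen on input ("_" = sn-position unresolved, "/" = resolved);
    ``header`` records whether the printed name carried a totals header, so
    formatting round-trips byte-for-byte.
    """

    lipid_class: LipidClassDef
    level: str
    total_carbons: int
    total_double_bonds: int
    total_oxygenation: int = 0
    acyls: tuple = ()
    separator: str = "_"
    header: bool = True
    header_prefix: str = ""
    raw_name: str = ""

    def __post_init__(self):
        if self.level not in (SUM_COMPOSITION, MOLECULAR_SPECIES):
            raise ValueError(f"unknown level {self.level!r}")
        if self.level == SUM_COMPOSITION and self.acyls:
            raise ValueError("sum-composition species must have empty acyls")
        if self.level == MOLECULAR_SPECIES and not self.acyls:
            raise ValueError("molecular-species level requires resolved chains")
        if self.acyls:
            c = sum(a.carbons for a in self.acyls)
            d = sum(a.double_bonds for a in self.acyls)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise ValueError(
                    "inconsistent composition: header "
                    f"{self.total_carbons}:{self.total_double_bonds} vs chain sum {c}:{d}"
                )

    @property
    def resolved(self) -> bool:
        return self.level == MOLECULAR_SPECIES

    @property
    def fatty_acyls(self) -> tuple:
        """Resolved fatty-acyl chains, excluding any sphingoid base."""
        return tuple(a for a in self.acyls if isinstance(a, AcylChain))

    @property
    def name(self) -> str:
        return format_lipid_name(self)


# ---------------------------------------------------------------------------
# class registry


class ClassRegistry:
    """Editable registry of lipid classes, loaded from a CSV table."""

    def __init__(self, classes: Iterable[LipidClassDef]):
        self._by_code = {}
        for c in classes:
            if c.code in self._by_code:
                raise ValueError(f"duplicate class code {c.code}")
            self._by_code[c.code] = c

    def __getitem__(self, code: str) -> LipidClassDef:
        return self._by_code[code]

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __iter__(self):
        return iter(self._by_code.values())

    def codes(self):
        return list(self._by_code)

    @classmethod
    def from_csv(cls, path) -> "ClassRegistry":
        import csv

        defs = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(_strip_comments(fh)):
                defs.append(
                    LipidClassDef(
                        code=row["code"].strip(),
                        acyl_slots=int(row["acyl_slots"]),
                        saponifiable_slots=int(row["saponifiable_slots"]),
                        category=row["category"].strip(),
                    )
                )
        return cls(defs)


def _strip_comments(lines):
    for ln in lines:
        if not ln.lstrip().startswith("#"):
            yield ln


_DEFAULT_REGISTRY = None


def default_registry() -> ClassRegistry:
    """Registry shipped with the package (data/lipid_classes.csv)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        with resources.as_file(
            resources.files("lipidtiers.data").joinpath("lipid_classes.csv")
        ) as p:
            _DEFAULT_REGISTRY = ClassRegistry.from_csv(p)
    return _DEFAULT_REGISTRY


# ---------------------------------------------------------------------------
# parsing

_CLASS_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\s*")
_TOTALS_RE = re.compile(r"^(O-|P-)?(\d+):(\d+)(;O(\d*))?")
_CHAIN_RE = re.compile(r"^(O-|P-|d|t)?(\d+):(\d+)(;O(\d*))?")


def _parse_oxy(group_flag, group_num) -> int:
    if group_flag is None:
        return 0
    return int(group_num) if group_num else 1


def _parse_chain(token: str, name: str, offset: int):
    m = _CHAIN_RE.match(token)
    if not m or m.end() != len(token):
        raise LipidNameError("parse error: malformed chain", name, offset)
    prefix, c, d, oflag, onum = m.groups()
    carbons, dbs = int(c), int(d)
    oxy = _parse_oxy(oflag, onum)
    try:
        if prefix in ("d", "t"):
            if oxy:
                raise LipidNameError("parse error: ;O on sphingoid base", name, offset)
            return SphingoidBase(carbons, dbs, hydroxyls=2 if prefix == "d" else 3)
        linkage = _PREFIX_LINKAGE.get(prefix, ESTER)
        return AcylChain(carbons, dbs, linkage=linkage, oxygenation=oxy)
    except ValueError as e:
        raise LipidNameError(f"parse error: {e}", name, offset) from e


def parse_lipid_name(name: str, registry: Optional[ClassRegistry] = None) -> LipidSpecies:
    """Parse a lipid shorthand name into a validated :class:`LipidSpecies`.

    Accepted shapes (class code resolved against ``registry``):

    * ``TG 52:3``                 — sum composition
    * ``SM 33:1;O2``              — sum composition with oxygenation
    * ``DG 36:3(18:2_18:1)``      — totals header + resolved chains
    * ``PE O-38:6(O-18:2_20:4)``  — ether species
    * ``Cer d18:1/17:0``          — bare chain list (standards dialect)
    * ``FA 16:0``                 — single-chain class, molecular species

    Raises :class:`LipidNameError` for unknown classes, malformed syntax,
    or a header/chain-sum mismatch.
    """
    registry = registry or default_registry()
    if not name or not name.strip():
        raise LipidNameError("parse error: empty name", name)
    text = name.strip()

    omega = None
    om = re.search(r"\s+(n-\d+)$", text)
    if om:
        omega = om.group(1)
        text = text[: om.start()]

    m = _CLASS_RE.match(text)
    if not m:
        raise LipidNameError("parse error: no class code", name, 0)
    code = m.group(1)
    if code not in registry:
        raise LipidNameError(f"unrecognized class {code!r}", name, 0)
    cls = registry[code]
    body = text[m.end():]
    body_off = len(name) - len(name.lstrip()) + m.end()
    if not body:
        raise LipidNameError("parse error: missing composition", name, body_off)

    # Bare chain list, e.g. "Cer d18:1/17:0", "PE 17:0/17:0", "FA 16:0"
    if "(" not in body:
        sep = "/" if "/" in body else ("_" if "_" in body else None)
        tokens = body.split(sep) if sep else [body]
        starts_sphingoid = bool(re.match(r"^[dt]\d", tokens[0]))
        single_chain_class = cls.acyl_slots == 1 and not cls.has_sphingoid_base
        if sep or (single_chain_class and not _is_totals_only(cls, body)):
            if starts_sphingoid or sep or single_chain_class:
                chains = tuple(
                    _parse_chain(t, name, body_off) for t in tokens
                )
                n_acyl = sum(isinstance(c, AcylChain) for c in chains)
                if cls.has_sphingoid_base and not any(
                    isinstance(c, SphingoidBase) for c in chains
                ):
                    raise LipidNameError(
                        "parse error: sphingolipid chain list lacks a d/t base",
                        name, body_off,
                    )
                if n_acyl > cls.acyl_slots:
                    raise LipidNameError(
                        f"inconsistent composition: {n_acyl} chains for class "
                        f"{code} with {cls.acyl_slots} slots", name, body_off,
                    )
                if omega is not None:
                    if n_acyl != 1:
                        raise LipidNameError(
                            "parse error: omega suffix only valid on a single chain",
                            name,
                        )
                    chains = tuple(
                        replace(c, omega_class=omega) if isinstance(c, AcylChain) else c
                        for c in chains
                    )
                return LipidSpecies(
                    lipid_class=cls,
                    level=MOLECULAR_SPECIES,
                    total_carbons=sum(c.carbons for c in chains),
                    total_double_bonds=sum(c.double_bonds for c in chains),
                    total_oxygenation=sum(
                        getattr(c, "oxygenation", 0) for c in chains
                    ),
                    acyls=chains,
                    separator=sep or "_",
                    header=False,
                    raw_name=name,
                )
        # totals-only header
        tm = _TOTALS_RE.match(body)
        if not tm or tm.end() != len(body):
            raise LipidNameError("parse error: malformed composition", name, body_off)
        if omega is not None:
            raise LipidNameError(
                "parse error: omega suffix needs a resolved chain", name
            )
        prefix, c, d, oflag, onum = tm.groups()
        return LipidSpecies(
            lipid_class=cls,
            level=SUM_COMPOSITION,
            total_carbons=int(c),
            total_double_bonds=int(d),
            total_oxygenation=_parse_oxy(oflag, onum),
            header_prefix=prefix or "",
            raw_name=name,
        )

    # totals header + parenthesised chain list
    if omega is not None:
        raise LipidNameError(
            "parse error: omega suffix not supported on multi-chain names", name
        )
    open_idx = body.index("(")
    header_txt = body[:open_idx].strip()
    if not body.endswith(")"):
        raise LipidNameError("parse error: unterminated chain list", name,
                             body_off + len(body) - 1)
    inner = body[open_idx + 1:-1]
    tm = _TOTALS_RE.match(header_txt)
    if not tm or tm.end() != len(header_txt):
        raise LipidNameError("parse error: malformed totals header", name, body_off)
    _, c, d, oflag, onum = tm.groups()
    tot_c, tot_d = int(c), int(d)
    tot_oxy = _parse_oxy(oflag, onum)
    sep = "/" if "/" in inner else "_"
    tokens = inner.split(sep) if (("/" in inner) or ("_" in inner)) else [inner]
    chains = tuple(_parse_chain(t, name, body_off + open_idx + 1) for t in tokens)
    n_acyl = sum(isinstance(ch, AcylChain) for ch in chains)
    if n_acyl > cls.acyl_slots:
        raise LipidNameError(
            f"inconsistent composition: {n_acyl} chains for class {code} "
            f"with {cls.acyl_slots} slots", name, body_off,
        )
    sum_c = sum(ch.carbons for ch in chains)
    sum_d = sum(ch.double_bonds for ch in chains)
    if (sum_c, sum_d) != (tot_c, tot_d):
        raise LipidNameError(
            f"inconsistent composition: header {tot_c}:{tot_d} "
            f"vs chain sum {sum_c}:{sum_d}", name, body_off,
        )
    return LipidSpecies(
        lipid_class=cls,
        level=MOLECULAR_SPECIES,
        total_carbons=tot_c,
        total_double_bonds=tot_d,
        total_oxygenation=tot_oxy,
        acyls=chains,
        separator=sep,
        header=True,
        raw_name=name,
    )


def _is_totals_only(cls: LipidClassDef, body: str) -> bool:
    """Single-chain classes: ``FA 16:0`` is a molecular species, but a
    sphingolipid like ``SM 33:1;O2`` keeps base+N-acyl folded into the
    totals, so a bare composition stays sum-composition there."""
    return cls.has_sphingoid_base


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_lipid_name`.

    Canonical form puts a single space after the class code and no space
    before the chain-list parenthesis; the chain separator and the
    header/bare-list style seen on input are preserved.
    """
    cls = species.lipid_class
    oxy = ""
    if species.total_oxygenation == 1:
        oxy = ";O"
    elif species.total_oxygenation > 1:
        oxy = f";O{species.total_oxygenation}"

    if species.level == SUM_COMPOSITION:
        return (
            f"{cls.code} {species.header_prefix}"
            f"{species.total_carbons}:{species.total_double_bonds}{oxy}"
        )

    chain_txt = species.separator.join(c.shorthand() for c in species.acyls)
    omega_sfx = ""
    if len(species.fatty_acyls) == 1 and species.fatty_acyls[0].omega_class:
        omega_sfx = f" {species.fatty_acyls[0].omega_class}"
    if not species.header:
        return f"{cls.code} {chain_txt}{omega_sfx}"
    if len(species.acyls) == 1 and not cls.has_sphingoid_base:
        return f"{cls.code} {chain_txt}{omega_sfx}"
    ether_prefix = ""
    n_eth = sum(1 for c in species.fatty_acyls if c.linkage == ETHER)
    n_vin = sum(1 for c in species.fatty_acyls if c.linkage == VINYL_ETHER)
    if n_vin:
        ether_prefix = "P-" if n_vin == 1 else f"{'d' if n_vin == 2 else 't'}P-"
    elif n_eth:
        ether_prefix = "O-" if n_eth == 1 else f"{'d' if n_eth == 2 else 't'}O-"
    header = f"{ether_prefix}{species.total_carbons}:{species.total_double_bonds}{oxy}"
    return f"{cls.code} {header}({chain_txt})"


def normalize_plasmalogen(species: LipidSpecies) -> LipidSpecies:
    """Rewrite vinyl-ether (P-) chains as O- with one extra double bond.

    Off by default everywhere: the shipped dialect reports names exactly as
    printed.  Provided for interoperability with O-only nomenclatures.
    """
    if not any(c.linkage == VINYL_ETHER for c in species.fatty_acyls):
        return species
    new = tuple(
        replace(c, linkage=ETHER, double_bonds=c.double_bonds + 1)
        if isinstance(c, AcylChain) and c.linkage == VINYL_ETHER
        else c
        for c in species.acyls
    )
    extra = sum(1 for c in species.fatty_acyls if c.linkage == VINYL_ETHER)
    return replace(
        species,
        acyls=new,
        total_double_bonds=species.total_double_bonds + extra,
        raw_name="",
    )


def acyl_multiplicity(
    species: LipidSpecies,
    fa: AcylChain,
    saponifiable_only: bool = True,
) -> int:
    """Number of chains in ``species`` matching ``fa``.

    A chain matches on (carbons, double_bonds, linkage, oxygenation);
    sphingoid bases never match.  With ``saponifiable_only`` (the default,
    matching alkaline-hydrolysis accounting) only ester-linked chains on
    classes whose slots hydrolyse are counted: sphingolipid N-acyls and
    ether/vinyl-ether chains contribute zero.

    Sum-composition species return 0; callers distinguish "unresolved" from
    "absent" via ``species.resolved``.
    """
    if not species.resolved:
        return 0
    cls = species.lipid_class
    if saponifiable_only and cls.saponifiable_slots == 0:
        return 0
    n = 0
    for chain in species.fatty_acyls:
        if saponifiable_only and chain.linkage != ESTER:
            continue
        if (
            chain.carbons == fa.carbons
            and chain.double_bonds == fa.double_bonds
            and chain.linkage == fa.linkage
            and chain.oxygenation == fa.oxygenation
        ):
            n += 1
    return n
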