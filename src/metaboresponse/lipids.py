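"""Lipid shorthand nomenclature: parsing, formatting and chain descriptors.

Supports the ``CLASS(c1:d1/c2:d2/...)`` and sum-composition ``CLASS(c:d)``
grammars used for annotated LC-MS lipid panels. Sphingolipid species write
their sphingoid base with a ``d`` prefix, e.g. ``SM(d18:1/18:0)``, where the
second chain is the N-acyl chain.

A name with explicit ``/``-separated chains is *sn-resolved*: the order of
chains encodes the sn-1/sn-2 positions for glycerophospholipids and the
(sphingoid base, N-acyl) pair for ceramides and sphingomyelins. Names such
as ``TG(48:1)`` give only the summed carbon and double-bond count and are
flagged ``sn_resolved=False``; downstream chain matching skips them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Chain",
    "LipidDescriptor",
    "LipidParseError",
    "parse_lipid_name",
    "format_lipid_name",
    "LIPID_CLASSES",
    "SPHINGOLIPID_CLASSES",
    "LYSOPHOSPHOLIPID_CLASSES",
    "VERY_LONG_CHAIN_CARBONS",
]

#: Recognised shorthand class tokens.
LIPID_CLASSES = ("FA", "CAR", "TG", "PC", "PE", "LPA", "LPC", "LPE", "LPI", "Cer", "SM")

#: Classes whose first chain is a sphingoid base (``d`` prefix).
SPHINGOLIPID_CLASSES = ("Cer", "SM")

#: Single-chain glycerophospholipid derivatives.
LYSOPHOSPHOLIPID_CLASSES = ("LPA", "LPC", "LPE", "LPI")

#: Chains with at least this many carbons count as very-long-chain species.
VERY_LONG_CHAIN_CARBONS = 24

_CANON = {c.upper(): c for c in LIPID_CLASSES}
_CHAIN_RE = re.compile(r"^(d?)(\d+):(\d+)$")
_NAME_RE = re.compile(r"^\s*([A-Za-z]+)\s*\(([^()]*)\)\s*$")


class LipidParseError(ValueError):
    """Raised by :func:`parse_lipid_name` in strict mode for bad shorthand."""


@dataclass(frozen=True)
class Chain:
    """One acyl chain (or sphingoid base) as ``carbons:double_bonds``."""

    carbons: int
    double_bonds: int
    sphingoid: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.double_bonds < 0:
            raise LipidParseError(f"negative chain composition {self}")
        if self.carbons < 2 * self.double_bonds:
            raise LipidParseError(
                f"chain {self.carbons}:{self.double_bonds} cannot carry "
                f"{self.double_bonds} double bonds"
            )

    @property
    def key(self) -> tuple[int, int]:
        return (self.carbons, self.double_bonds)

    def __str__(self) -> str:
        prefix = "d" if self.sphingoid else ""
        return f"{prefix}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidDescriptor:
    """Parsed lipid species: class token plus chain composition."""

    lipid_class: str
    chains: tuple[Chain, ...]
    sn_resolved: bool = True

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise LipidParseError(f"unknown lipid class {self.lipid_class!r}")
        if not self.chains:
            raise LipidParseError("descriptor needs at least one chain")
        if self.sn_resolved and self.lipid_class in SPHINGOLIPID_CLASSES:
            if len(self.chains) != 2:
                raise LipidParseError(
                    f"{self.lipid_class} needs sphingoid base + N-acyl chain"
                )
            if not self.chains[0].sphingoid:
                raise LipidParseError(
                    f"{self.lipid_class} first chain must be the d-prefixed base"
                )

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)

    @property
    def very_long_chain(self) -> bool:
        """True when any non-sphingoid chain has >= 24 carbons."""
        return any(
            c.carbons >= VERY_LONG_CHAIN_CARBONS
            for c in self.chains
            if not c.sphingoid
        )

    def __str__(self) -> str:
        return format_lipid_name(self)


def _parse_chain(token: str, expect_sphingoid: bool) -> Chain:
    m = _CHAIN_RE.match(token.strip())
    if m is None:
        raise LipidParseError(f"bad chain token {token!r}")
    sphingoid = m.group(1) == "d"
    if sphingoid and not expect_sphingoid:
        raise LipidParseError(f"unexpected sphingoid prefix in {token!r}")
    return Chain(int(m.group(2)), int(m.group(3)), sphingoid=sphingoid)


def parse_lipid_name(name: str, strict: bool = False) -> LipidDescriptor | None:
    """Parse a shorthand lipid name into a :class:`LipidDescriptor`.

    Parameters
    ----------
    name
        e.g. ``"PC(16:0/20:4)"``, ``"SM(d18:1/18:0)"``, ``"TG(48:1)"``,
        ``"FA(16:0)"``. The class token is matched case-insensitively and
        normalised to the canonical casing.
    strict
        When False (default) an unparseable name yields ``None`` with a
        warning, so unannotated or free-text feature names survive ingest.
        When True a :class:`LipidParseError` is raised instead.

    Returns
    -------
    LipidDescriptor or None
        ``sn_resolved`` is True iff the name separates chains with ``/``.
    """
    try:
        m = _NAME_RE.match(name or "")
        if m is None:
            raise LipidParseError(f"not lipid shorthand: {name!r}")
        cls = _CANON.get(m.group(1).upper())
        if cls is None:
            raise LipidParseError(f"unknown lipid class in {name!r}")
        tokens = [t for t in m.group(2).split("/")]
        sn_resolved = len(tokens) > 1
        chains = tuple(
            _parse_chain(tok, expect_sphingoid=(i == 0 and cls in SPHINGOLIPID_CLASSES))
            for i, tok in enumerate(tokens)
        )
        if cls in SPHINGOLIPID_CLASSES and sn_resolved and not chains[0].sphingoid:
            raise LipidParseError(f"{cls} base chain must carry the d prefix: {name!r}")
        # Single-chain classes are chain-resolved by construction.
        if cls in ("FA", "CAR") or cls in LYSOPHOSPHOLIPID_CLASSES:
            if len(chains) != 1:
                raise LipidParseError(f"{cls} carries exactly one chain: {name!r}")
            sn_resolved = True
        return LipidDescriptor(cls, chains, sn_resolved=sn_resolved)
    except LipidParseError:
        if strict:
            raise
        warnings.warn(f"unparseable lipid shorthand {name!r}; kept unannotated",
                      stacklevel=2)
        return None


def format_lipid_name(d: LipidDescriptor) -> str:
    """Inverse of :func:`parse_lipid_name` for valid descriptors."""
    body = "/".join(str(c) for c in d.chains)
    return f"{d.lipid_class}({body})"
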