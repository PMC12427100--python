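"""Lipid shorthand nomenclature: parsing and characteristic annotation.

Shotgun-lipidomics species names follow the shorthand grammar

    CLASS[ O-] C:D[;H][/C:D[;H] ...]

where ``CLASS`` is a headgroup token (PC, PE, TAG, Cer, ...), an ``O-``
suffix marks ether linkage at sn-1 (alkyl or alkenyl/plasmalogen bond),
``C`` counts acyl/alkyl carbons, ``D`` double bonds and the optional
``;H`` hydroxyl groups (sphingolipids).  A single C:D token is a *sum
composition* (total carbons/double bonds only, no per-chain resolution);
multiple ``/``-separated tokens give per-chain resolution.

Downstream enrichment works on four characteristics derived here: lipid
class, ether linkage, total chain length and total double-bond count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import MalformedNameError, UnknownClassError

logger = logging.getLogger(__name__)

#: Headgroup vocabulary.  Ether variants carry the "O-" suffix; only the
#: classes with an ether analogue monitored in shotgun acquisitions are listed.
CLASS_VOCABULARY: tuple[str, ...] = (
    "CL", "Cer", "DAG", "HexCer", "LPA", "LPC", "LPE", "LPG", "LPI", "LPS",
    "PA", "PC", "PE", "PG", "PI", "PS", "CE", "SM", "TAG",
    "PC O-", "PE O-", "LPC O-", "LPE O-",
)

ETHER_CLASSES: frozenset[str] = frozenset(c for c in CLASS_VOCABULARY if c.endswith("O-"))

# longest-first so "PC O-" wins over "PC"
_CLASSES_BY_LENGTH = sorted(CLASS_VOCABULARY, key=len, reverse=True)

_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:;(\d+))?$")


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed identity of one lipid species.

    ``chains`` is empty when only a sum composition was given; otherwise the
    totals are the element-wise sums over the chains.
    """

    raw_name: str
    lipid_class: str
    ether_linked: bool
    total_carbons: int
    total_double_bonds: int
    total_hydroxyls: int
    chains: tuple[tuple[int, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.lipid_class not in CLASS_VOCABULARY:
            raise UnknownClassError(self.raw_name)
        if self.ether_linked != self.lipid_class.endswith("O-"):
            raise ValueError("ether_linked inconsistent with class token")
        if self.chains:
            sums = tuple(sum(ch[i] for ch in self.chains) for i in range(3))
            if sums != (self.total_carbons, self.total_double_bonds, self.total_hydroxyls):
                raise ValueError("chain sums do not match totals")
        if self.total_carbons <= 0:
            raise ValueError("total_carbons must be positive")


def _normalize(name: str) -> str:
    # MS vendor tables print the ether suffix with hyphen, en-dash or minus sign
    return name.replace("O–", "O-").replace("O−", "O-").strip()


def parse_species(name: str) -> LipidSpecies:
    """Parse one shorthand name into a :class:`LipidSpecies`.

    Raises :class:`UnknownClassError` if the leading class token is not in
    :data:`CLASS_VOCABULARY`, and :class:`MalformedNameError` if the C:D
    composition cannot be read.
    """
    if not name or not name.strip():
        raise MalformedNameError(name, "empty name")
    norm = _normalize(name)

    lipid_class = None
    rest = ""
    for cls in _CLASSES_BY_LENGTH:
        if norm == cls:
            lipid_class, rest = cls, ""
            break
        if norm.startswith(cls):
            nxt = norm[len(cls):]
            # class token must end at a boundary: space, or digits right after "O-"
            if cls.endswith("O-") or nxt[:1] == " ":
                lipid_class, rest = cls, nxt.strip()
                break
    if lipid_class is None:
        raise UnknownClassError(name)
    if not rest:
        raise MalformedNameError(name, "no composition token")

    chains: list[tuple[int, int, int]] = []
    for tok in rest.split("/"):
        m = _CHAIN_RE.match(tok.strip())
        if m is None:
            raise MalformedNameError(name, f"bad composition token {tok!r}")
        c, d, h = int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)
        chains.append((c, d, h))
    if any(c == 0 for c, _, _ in chains):
        raise MalformedNameError(name, "zero-carbon chain")

    totals = tuple(sum(ch[i] for ch in chains) for i in range(3))
    explicit = len(chains) > 1
    return LipidSpecies(
        raw_name=name,
        lipid_class=lipid_class,
        ether_linked=lipid_class in ETHER_CLASSES,
        total_carbons=totals[0],
        total_double_bonds=totals[1],
        total_hydroxyls=totals[2],
        chains=tuple(chains) if explicit else (),
    )


def format_species(sp: LipidSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_species`."""

    def fmt_chain(c: int, d: int, h: int) -> str:
        return f"{c}:{d};{h}" if h else f"{c}:{d}"

    if sp.chains:
        comp = "/".join(fmt_chain(*ch) for ch in sp.chains)
    else:
        comp = fmt_chain(sp.total_carbons, sp.total_double_bonds, sp.total_hydroxyls)
    sep = "" if sp.lipid_class.endswith("O-") else " "
    return f"{sp.lipid_class}{sep}{comp}"


def parse_many(
    names: Iterable[str], strict: bool = False
) -> tuple[list[LipidSpecies], list[str]]:
    """Parse a batch of names.

    In lenient mode (default) unparseable names are dropped with a logged
    warning and returned in the second element; in strict mode the first
    failure propagates.
    """
    parsed: list[LipidSpecies] = []
    failed: list[str] = []
    for name in names:
        try:
            parsed.append(parse_species(name))
        except (UnknownClassError, MalformedNameError):
            if strict:
                raise
            failed.append(name)
    if failed:
        logger.warning("dropped %d unparseable lipid names (e.g. %r)", len(failed), failed[0])
    return parsed, failed


def _bin_label(value: int, boundaries: Sequence[int] | None) -> str:
    """Half-open bins [lo, hi) from 0 through the boundaries, final bin open-ended."""
    if boundaries is None:
        return str(value)
    edges = [0, *boundaries]
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= value < hi:
            return f"[{lo},{hi})"
    return f"[{edges[-1]},inf)"


def characteristic_table(
    species: Iterable[LipidSpecies],
    chain_bins: Sequence[int] | None = None,
    db_bins: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Annotate species with the characteristics used by enrichment.

    Returns a DataFrame indexed by ``raw_name`` with columns ``class``,
    ``ether_linked``, ``chain_bin`` and ``db_bin``.  Bin boundaries must be
    strictly increasing positive integers; bins are half-open ``[lo, hi)``
    starting at 0 with an open-ended final bin.  With ``None`` boundaries
    every observed integer value is its own bin (unit-width default).
    """
    for bins in (chain_bins, db_bins):
        if bins is not None and any(b <= a for a, b in zip(bins, bins[1:])):
            raise ValueError("bin boundaries must be strictly increasing")
        if bins is not None and bins[0] <= 0:
            raise ValueError("bin boundaries must be positive")

    rows = {
        sp.raw_name: {
            "class": sp.lipid_class,
            "ether_linked": sp.ether_linked,
            "chain_bin": _bin_label(sp.total_carbons, chain_bins),
            "db_bin": _bin_label(sp.total_double_bonds, db_bins),
        }
        for sp in species
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "species_id"
    return table
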