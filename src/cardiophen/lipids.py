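"""Lipid-species parsing, mTIC normalization and class summaries.

Species names follow the compact dialect used for cardiolipin (CL) and
fatty-acid annotations:

* ``CL(18:1/18:1/18:2/18:2)`` — four acyl chains, carbons:double-bonds;
* ``[18:1][18:1][18:2][18:2]`` — CL bracket shorthand;
* ``tetra[18:2]-CL`` — four identical chains (the mature cardiac species);
* ``MLCL(18:2/18:2/18:2)`` — monolyso-CL, three chains;
* ``TG(16:0/18:1/18:2)`` — triglycerides;
* ``AC(16:0)``, ``AC(16:0-OH)`` — acyl-carnitines, optionally hydroxylated;
* ``FFA(18:1)``, ``FFA(16:0-OH)`` — free fatty acids.

mTIC normalization scales each sample so that its summed signal over
*identified* species equals the cross-sample mean of those sums; unknown
features in the same sample are scaled by the same factor.  Class summaries
implement the study's standard panels: long-chain (>= 14 carbons) and
hydroxylated acyl-carnitine sums, triglyceride totals, CLs containing a given
chain, the tetra[18:2]-CL fraction of total CL, and per-species fold changes
against a reference group.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "LONG_CHAIN_MIN_CARBONS",
    "MEDIUM_CHAIN_RANGE",
    "Chain",
    "LipidSpecies",
    "LipidParseError",
    "LipidTable",
    "parse_lipid_name",
    "render_lipid_name",
    "mtic_normalize",
    "presence_filter",
    "class_sum",
    "cl_contains_chain",
    "tetra_cl_fraction",
    "fold_change",
    "class_summaries",
]

#: "Long-chain" acyl chains have at least this many carbons.
LONG_CHAIN_MIN_CARBONS = 14
#: "Medium-chain" span (inclusive) in carbons.
MEDIUM_CHAIN_RANGE = (6, 12)

#: Required chain counts per class (None = unconstrained).
_CHAIN_COUNTS = {"CL": 4, "MLCL": 3, "TG": 3, "AC": 1, "FFA": 1, "other": None}


class Chain(NamedTuple):
    """One acyl chain: carbon count, double bonds, hydroxylation flag."""

    carbons: int
    double_bonds: int
    hydroxyl: bool = False


@dataclass
class LipidSpecies:
    """A parsed lipid species; equality ignores the raw spelling."""

    raw_name: str = field(compare=False)
    lipid_class: str
    chains: tuple[Chain, ...]

    def __post_init__(self) -> None:
        self.chains = tuple(self.chains)
        expected = _CHAIN_COUNTS.get(self.lipid_class)
        if self.lipid_class not in _CHAIN_COUNTS:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if expected is not None and len(self.chains) != expected:
            raise ValueError(
                f"{self.lipid_class} requires {expected} chains, "
                f"got {len(self.chains)}"
            )
        for ch in self.chains:
            if ch.carbons <= 0:
                raise ValueError("chain carbons must be positive")
            if ch.double_bonds < 0:
                raise ValueError("double bonds must be non-negative")

    @property
    def hydroxylated(self) -> bool:
        return any(ch.hydroxyl for ch in self.chains)

    @property
    def total_carbons(self) -> int:
        return sum(ch.carbons for ch in self.chains)


class LipidParseError(ValueError):
    """Unparseable lipid name; carries the failure position."""

    def __init__(self, raw: str, position: int, message: str) -> None:
        super().__init__(f"cannot parse {raw!r} at position {position}: {message}")
        self.raw = raw
        self.position = position


_CHAIN_RE = re.compile(r"(\d+):(\d+)(-OH)?")
_TETRA_RE = re.compile(r"tetra\[(\d+):(\d+)\]-CL$")
_BRACKET_RE = re.compile(r"^(\[\d+:\d+\]){4}$")
_CLASS_RE = re.compile(r"^(CL|MLCL|TG|AC|FFA)\((.*)\)$")


def _parse_chain(text: str, raw: str, offset: int) -> Chain:
    m = _CHAIN_RE.fullmatch(text)
    if not m:
        raise LipidParseError(raw, offset, f"bad chain spec {text!r}")
    return Chain(int(m.group(1)), int(m.group(2)), m.group(3) is not None)


def parse_lipid_name(raw: str) -> LipidSpecies:
    """Parse a species name in the documented grammar.

    Raises
    ------
    LipidParseError
        With the offending position, for names outside the grammar
        (including chain-count violations such as a two-chain CL).
    """
    name = raw.strip()
    m = _TETRA_RE.fullmatch(name)
    if m:
        chain = Chain(int(m.group(1)), int(m.group(2)), False)
        return LipidSpecies(raw, "CL", (chain,) * 4)
    if name.startswith("["):
        if not _BRACKET_RE.fullmatch(name):
            n_open = name.count("[")
            raise LipidParseError(
                raw, 0, f"CL bracket shorthand needs exactly 4 chains, saw {n_open}"
            )
        chains = tuple(
            Chain(int(a), int(b), False)
            for a, b in re.findall(r"\[(\d+):(\d+)\]", name)
        )
        return LipidSpecies(raw, "CL", chains)
    m = _CLASS_RE.fullmatch(name)
    if m:
        cls, body = m.group(1), m.group(2)
        offset = len(cls) + 1
        parts = body.split("/")
        chains = []
        for part in parts:
            chains.append(_parse_chain(part, raw, offset))
            offset += len(part) + 1
        expected = _CHAIN_COUNTS[cls]
        if expected is not None and len(chains) != expected:
            raise LipidParseError(
                raw, len(cls) + 1,
                f"{cls} requires {expected} chains, got {len(chains)}",
            )
        return LipidSpecies(raw, cls, tuple(chains))
    raise LipidParseError(raw, 0, "name matches no known grammar production")


def render_lipid_name(species: LipidSpecies) -> str:
    """Canonical spelling: ``CLASS(c:d/.../c:d)`` with ``-OH`` suffixes."""
    body = "/".join(
        f"{ch.carbons}:{ch.double_bonds}" + ("-OH" if ch.hydroxyl else "")
        for ch in species.chains
    )
    return f"{species.lipid_class}({body})"


@dataclass
class LipidTable:
    """Species x samples abundance table with group labels.

    ``abundance`` rows are raw species names; ``groups`` maps sample to group
    label; ``identified`` flags species with a confirmed identity (unknown
    features carry the flag False and are excluded from mTIC sums and class
    summaries).  Parsed species are available as ``species`` (unknowns map to
    ``None``).
    """

    abundance: pd.DataFrame
    groups: pd.Series
    identified: pd.Series | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.abundance.values < 0).any():
            raise ValueError("abundances must be non-negative")
        self.groups = pd.Series(self.groups).loc[self.abundance.columns]
        if self.identified is None:
            self.identified = pd.Series(True, index=self.abundance.index)
        else:
            self.identified = pd.Series(self.identified).loc[self.abundance.index]
        if not self.identified.any():
            raise ValueError("table must contain at least one identified species")
        self.species: dict[str, LipidSpecies | None] = {}
        for name in self.abundance.index:
            if self.identified[name]:
                self.species[name] = parse_lipid_name(name)
            else:
                self.species[name] = None

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def select(self, predicate: Callable[[LipidSpecies], bool]) -> pd.DataFrame:
        """Rows whose parsed species satisfy the predicate."""
        names = [
            n for n, sp in self.species.items() if sp is not None and predicate(sp)
        ]
        return self.abundance.loc[names]


def mtic_normalize(table: LipidTable) -> LipidTable:
    """Scale each sample so its identified-species sum equals the cross-sample
    mean of those sums (mTIC normalization); unknowns scale along."""
    known = table.abundance.loc[table.identified]
    sums = known.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"zero identified-species signal in samples {bad}")
    factors = sums.mean() / sums
    return replace(table, abundance=table.abundance * factors, normalized=True)


def presence_filter(
    table: LipidTable, min_fraction: float = 0.5, *, mode: str = "all"
) -> LipidTable:
    """Keep features present (abundance > 0) in at least ``min_fraction`` of
    samples of each group (``mode="all"``) or of any group (``mode="any"``)."""
    present = table.abundance > 0
    frac = present.T.groupby(table.groups).mean().T  # species x groups
    if mode == "all":
        keep = (frac >= min_fraction).all(axis=1)
    elif mode == "any":
        keep = (frac >= min_fraction).any(axis=1)
    else:
        raise ValueError("mode must be 'all' or 'any'")
    return replace(
        table,
        abundance=table.abundance.loc[keep],
        identified=table.identified.loc[keep],
    )


def class_sum(
    table: LipidTable,
    lipid_class: str,
    *,
    min_carbons: int | None = None,
    max_carbons: int | None = None,
    hydroxylated: bool | None = None,
) -> pd.Series:
    """Per-sample sum over one class, with optional per-chain carbon range and
    hydroxylation predicates (a species matches if any chain matches the
    carbon range; hydroxylation refers to the species)."""

    def pred(sp: LipidSpecies) -> bool:
        if sp.lipid_class != lipid_class:
            return False
        if hydroxylated is not None and sp.hydroxylated != hydroxylated:
            return False
        if min_carbons is None and max_carbons is None:
            return True
        lo = 0 if min_carbons is None else min_carbons
        hi = np.inf if max_carbons is None else max_carbons
        return any(lo <= ch.carbons <= hi for ch in sp.chains)

    return table.select(pred).sum(axis=0)


def cl_contains_chain(
    table: LipidTable, carbons: int, double_bonds: int | None = None
) -> pd.Series:
    """Per-sample sum of CL species with at least one matching acyl chain
    (``double_bonds=None`` matches any saturation)."""

    def pred(sp: LipidSpecies) -> bool:
        return sp.lipid_class == "CL" and any(
            ch.carbons == carbons
            and (double_bonds is None or ch.double_bonds == double_bonds)
            for ch in sp.chains
        )

    return table.select(pred).sum(axis=0)


def tetra_cl_fraction(
    table: LipidTable, carbons: int = 18, double_bonds: int = 2
) -> pd.Series:
    """Per-sample abundance of the tetra-acyl CL (default tetra[18:2]-CL)
    as a fraction of total CL."""
    target = Chain(carbons, double_bonds, False)
    tetra = table.select(
        lambda sp: sp.lipid_class == "CL" and all(ch == target for ch in sp.chains)
    ).sum(axis=0)
    total = class_sum(table, "CL")
    with np.errstate(invalid="ignore"):
        return tetra / total


def fold_change(
    table: LipidTable, reference_group: str
) -> tuple[pd.DataFrame, list[str]]:
    """Species x samples fold-change matrix against the reference-group mean.

    Reference-group columns average to 1 per species by construction.
    Species whose reference mean is zero cannot be normalized: their rows are
    NaN and their names returned as flagged.
    """
    ref_samples = [s for s in table.samples if table.groups[s] == reference_group]
    if not ref_samples:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    ref_mean = table.abundance[ref_samples].mean(axis=1)
    flagged = list(ref_mean.index[ref_mean == 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = table.abundance.div(ref_mean.replace(0, np.nan), axis=0)
    return fc, flagged


def class_summaries(table: LipidTable, reference_group: str | None = None) -> dict:
    """The study's standard summary panel.

    Returns per-sample Series keyed by panel name: long-chain and
    medium-chain acyl-carnitine sums, hydroxylated long-chain acyl-carnitine
    and FFA sums, triglyceride totals, CLs containing 14:0 or 16:0 chains,
    CLs with any chain of >= 20 carbons, and the tetra[18:2]-CL fraction;
    plus the per-species fold-change matrix when a reference group is given.
    """
    lo_med, hi_med = MEDIUM_CHAIN_RANGE
    out = {
        "long_chain_acylcarnitines": class_sum(
            table, "AC", min_carbons=LONG_CHAIN_MIN_CARBONS
        ),
        "medium_chain_acylcarnitines": class_sum(
            table, "AC", min_carbons=lo_med, max_carbons=hi_med
        ),
        "hydroxylated_long_chain_acylcarnitines": class_sum(
            table, "AC", min_carbons=LONG_CHAIN_MIN_CARBONS, hydroxylated=True
        ),
        "hydroxylated_ffas": class_sum(table, "FFA", hydroxylated=True),
        "triglycerides": class_sum(table, "TG"),
        "cl_with_14_0": cl_contains_chain(table, 14, 0),
        "cl_with_16_0": cl_contains_chain(table, 16, 0),
        "cl_chain_ge20": class_sum(table, "CL", min_carbons=20),
        "tetra_18_2_cl_fraction": tetra_cl_fraction(table),
    }
    if reference_group is not None:
        fc, flagged = fold_change(table, reference_group)
        out["fold_change"] = fc
        out["fold_change_flagged"] = flagged
    return out
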