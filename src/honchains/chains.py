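"""Causal-factor taxonomy and accident-chain data model.

An accident causal chain is an ordered sequence of coded causal factors,
for example ``H10→H05→A1→A6`` (unfamiliar road → improper overtaking →
collision → leakage).  Factors are drawn from a fixed taxonomy of 67
atomic causes in six families — Human (H), Vehicle (V), Hazardous
Materials (HM), Management (M), Environment (E) and Accident type (A) —
plus composite multi-factor codes formed by concatenating compact atomic
codes (``E3H3`` = turning road acting together with fast driving).

This module defines the factor registry, canonicalization and parsing of
factor codes (atomic and composite), and reading/writing of plain-text
chain files (one chain per line, ``→``-separated, ``#`` comments).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("honchains")

__all__ = [
    "CausalFactor",
    "AccidentChain",
    "REGISTRY",
    "FAMILIES",
    "canonicalize_code",
    "compact_code",
    "parse_factor",
    "parse_chain_line",
    "load_chains",
    "save_chains",
    "export_registry_csv",
    "ChainParseError",
]


class ChainParseError(ValueError):
    """Raised for unknown codes, untokenizable composites or malformed lines."""


# --------------------------------------------------------------------------
# Factor registry: the 67 atomic causes.
#
# Canonical forms: the accident-type family uses single digits (A1..A9);
# every other family is two-digit zero-padded (H01, V04, HM03, ...).
# --------------------------------------------------------------------------

_REGISTRY_ROWS: list[tuple[str, str, str]] = [
    # Human (H): unsafe behaviours during transport
    ("H01", "H", "Fatigue driving"),
    ("H02", "H", "Improper avoidance"),
    ("H03", "H", "Fast driving"),
    ("H04", "H", "Improper braking"),
    ("H05", "H", "Improper overtaking"),
    ("H06", "H", "Improper operation"),
    ("H07", "H", "Overload transportation"),
    ("H08", "H", "Distracted driving"),
    ("H09", "H", "Unsafe distance"),
    ("H10", "H", "Unfamiliar with the road"),
    ("H11", "H", "Other hazmat personnel reasons"),
    ("H12", "H", "Non-hazmat personnel reasons"),
    # Vehicle (V)
    ("V01", "V", "Tank equipment failure"),
    ("V02", "V", "Valve loose"),
    ("V03", "V", "Valve damaged"),
    ("V04", "V", "Tank damaged"),
    ("V05", "V", "Tank/valve aging"),
    ("V06", "V", "Pipe rupture"),
    ("V07", "V", "Other tank reasons"),
    ("V08", "V", "Blow-out"),
    ("V09", "V", "Transmission shaft fracture"),
    ("V10", "V", "Brake system fault"),
    ("V11", "V", "Vehicle out of control"),
    ("V12", "V", "Tire overheating"),
    ("V13", "V", "Equipment aging"),
    ("V14", "V", "Oil tank damaged"),
    ("V15", "V", "Other vehicle reasons"),
    ("V16", "V", "Packaging issues"),
    # Hazardous materials (HM)
    ("HM01", "HM", "Explosive materials"),
    ("HM02", "HM", "Gas"),
    ("HM03", "HM", "Flammable liquid"),
    ("HM04", "HM", "Flammable solid"),
    ("HM05", "HM", "Oxidizing materials"),
    ("HM06", "HM", "Toxic and infectious materials"),
    ("HM07", "HM", "Radioactive materials"),
    ("HM08", "HM", "Corrosive and irritant materials"),
    ("HM09", "HM", "Miscellaneous hazmat"),
    # Management (M)
    ("M01", "M", "Illegally refitting vehicles"),
    ("M02", "M", "No supercargo"),
    ("M03", "M", "Failure to clean tank as required"),
    ("M04", "M", "Illegal transportation"),
    ("M05", "M", "No hazmat qualification certificate"),
    ("M06", "M", "No hazmat transportation license"),
    ("M07", "M", "Inadequate safety check"),
    ("M08", "M", "Other management reasons"),
    # Environment (E)
    ("E01", "E", "Downhill road"),
    ("E02", "E", "Slippery road"),
    ("E03", "E", "Turning road"),
    ("E04", "E", "Poor road"),
    ("E05", "E", "Other road reasons"),
    ("E06", "E", "Traffic jam"),
    ("E07", "E", "Multi-car collision"),
    ("E08", "E", "Other traffic reasons"),
    ("E09", "E", "Rain or snow weather"),
    ("E10", "E", "Foggy weather"),
    ("E11", "E", "High temperature"),
    ("E12", "E", "Poor visibility"),
    ("E13", "E", "Other environment reasons"),
    # Accident type (A)
    ("A1", "A", "Collision"),
    ("A2", "A", "Scrape"),
    ("A3", "A", "Roll-over"),
    ("A4", "A", "Fall-over"),
    ("A5", "A", "Fire"),
    ("A6", "A", "Leakage"),
    ("A7", "A", "Explosion"),
    ("A8", "A", "Poisoning"),
    ("A9", "A", "Others"),
]

#: canonical code -> (category, label)
REGISTRY: dict[str, tuple[str, str]] = {
    code: (cat, label) for code, cat, label in _REGISTRY_ROWS
}

#: family prefix -> (largest valid number, zero-padding width of the canonical form)
FAMILIES: dict[str, tuple[int, int]] = {
    "H": (12, 2),
    "V": (16, 2),
    "HM": (9, 2),
    "M": (8, 2),
    "E": (13, 2),
    "A": (9, 1),
}

_CODE_RE = re.compile(r"^([A-Z]+)0*([0-9]+)$")


def canonicalize_code(raw: str) -> str:
    """Normalize a single atomic factor code to its canonical registry form.

    Zero-padding is normalized in both directions: ``A01`` → ``A1`` (the
    accident-type family is single-digit) and ``H1`` → ``H01`` (all other
    families are two-digit).

    Raises
    ------
    ChainParseError
        If the prefix is not a known family or the number is out of range.
    """
    token = raw.strip()
    m = _CODE_RE.match(token)
    if not m:
        raise ChainParseError(f"unrecognizable factor code: {raw!r}")
    family, digits = m.group(1), m.group(2)
    if family not in FAMILIES:
        raise ChainParseError(f"unknown factor family {family!r} in code {raw!r}")
    number = int(digits)
    hi, width = FAMILIES[family]
    if not 1 <= number <= hi:
        raise ChainParseError(
            f"factor number out of range in code {raw!r}: {family} family has 1..{hi}"
        )
    return f"{family}{number:0{width}d}"


def compact_code(canonical: str) -> str:
    """Compact form used inside composite codes: padding stripped (E03 → E3)."""
    m = _CODE_RE.match(canonical)
    assert m is not None
    return f"{m.group(1)}{int(m.group(2))}"


@dataclass(frozen=True)
class CausalFactor:
    """One coded cause: either an atomic registry entry or a composite.

    A composite represents simultaneous action of two or more atomic
    causes and is an opaque unit: it is never linked to or merged with
    its atomic parts anywhere downstream.
    """

    code: str
    category: str
    label: str
    parts: tuple[str, ...]

    @property
    def is_composite(self) -> bool:
        return len(self.parts) > 1

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def _tokenize_composite(code: str) -> list[str]:
    """Greedy left-to-right longest-match split into canonical atomic codes."""
    tokens: list[str] = []
    i = 0
    s = code.strip()
    while i < len(s):
        m = re.match(r"([A-Z]+)([0-9]+)", s[i:])
        if not m:
            raise ChainParseError(f"cannot tokenize composite code {code!r} at {s[i:]!r}")
        family, digits = m.group(1), m.group(2)
        if family not in FAMILIES:
            raise ChainParseError(f"unknown factor family {family!r} in {code!r}")
        # longest digit run that forms an in-range code wins
        canon = None
        taken = 0
        for take in range(len(digits), 0, -1):
            try:
                canon = canonicalize_code(family + digits[:take])
            except ChainParseError:
                continue
            taken = take
            break
        if canon is None:
            raise ChainParseError(f"no valid factor number for {family!r} in {code!r}")
        tokens.append(canon)
        i += len(family) + taken
    return tokens


def parse_factor(code: str) -> CausalFactor:
    """Parse an atomic or composite factor code into a :class:`CausalFactor`.

    Atomic codes are canonicalized against the registry.  Concatenations of
    compact codes ("E3H3", "A6HM3") yield a COMPOSITE factor whose parts are
    the canonical atomic codes in input order; the composite's own code is
    the concatenation of the compact forms of its parts.
    """
    parts = _tokenize_composite(code)
    if len(parts) == 1:
        canon = parts[0]
        cat, label = REGISTRY[canon]
        return CausalFactor(code=canon, category=cat, label=label, parts=(canon,))
    if len(set(parts)) < len(parts):
        raise ChainParseError(f"composite code {code!r} repeats an atomic part")
    comp_code = "".join(compact_code(p) for p in parts)
    comp_label = " + ".join(REGISTRY[p][1] for p in parts)
    return CausalFactor(
        code=comp_code, category="COMPOSITE", label=comp_label, parts=tuple(parts)
    )


@dataclass(frozen=True)
class AccidentChain:
    """Ordered causal path of one accident (at least two factors)."""

    factors: tuple[CausalFactor, ...]
    source_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.factors) < 2:
            raise ChainParseError(
                f"accident chain needs >= 2 factors, got {len(self.factors)}"
            )

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(f.code for f in self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    def __iter__(self):
        return iter(self.factors)


_DELIMITERS = ("→", "->", ",")


def parse_chain_line(line: str, source_id: str | None = None) -> AccidentChain:
    """Parse one chain line, e.g. ``H10→H05→A01→A06``.

    The arrow ``→`` is the canonical delimiter; ``->`` and ``,`` are
    accepted dialects.  All factors are canonicalized.
    """
    text = line.strip()
    for delim in _DELIMITERS:
        if delim in text:
            raw_tokens = text.split(delim)
            break
    else:
        raw_tokens = [text] if text else []
    tokens = [t.strip() for t in raw_tokens if t.strip()]
    if len(tokens) < 2:
        raise ChainParseError(f"chain needs >= 2 factors: {line!r}")
    return AccidentChain(
        factors=tuple(parse_factor(t) for t in tokens), source_id=source_id
    )


def load_chains(path: str | Path, strict: bool = True) -> list[AccidentChain]:
    """Load a chain file: one chain per non-empty, non-comment line.

    In strict mode (default) any malformed line aborts with its line
    number; in lenient mode malformed lines are skipped with a warning.
    """
    path = Path(path)
    chains: list[AccidentChain] = []
    skipped = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                chains.append(parse_chain_line(text, source_id=f"{path.name}:{lineno}"))
            except ChainParseError as exc:
                if strict:
                    raise ChainParseError(f"line {lineno}: {exc}") from exc
                skipped += 1
                logger.warning("skipping malformed line %d of %s: %s", lineno, path, exc)
    if not chains:
        logger.warning("no chains parsed from %s", path)
    logger.info("loaded %d chains from %s (%d lines skipped)", len(chains), path, skipped)
    return chains


def save_chains(chains: Iterable[AccidentChain], path: str | Path) -> None:
    """Write chains one per line with the canonical ``→`` delimiter."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for chain in chains:
            fh.write("→".join(chain.codes) + "\n")


def export_registry_csv(path: str | Path) -> None:
    """Export the atomic-cause registry as CSV (code,category,label)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "category", "label"])
        for code, cat, label in _REGISTRY_ROWS:
            writer.writerow([code, cat, label])
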