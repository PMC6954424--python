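"""Barcode oligonucleotide layout for HaloTag protein barcoding.

Each protein in the assay is covalently linked (HaloTag ligand, 1:1
stoichiometry) to a 100-mer single-stranded DNA barcode laid out as::

    5'-[amplification arm, 31 bp][protein identifier, 8 bp]
       [counting tag, 30 bp][amplification arm, 31 bp]-3'

The 8-bp *protein identifier* names which protein a read reports.  The
30-bp *counting tag* is semi-random: 24 random bases interleaved with 6
invariant ("fixed") bases.  Distinct counting tags enumerate individual
protein molecules; the fixed bases act as an internal fidelity control
used to discard low-quality reads before molecule counting.  Sequencing
reads the 38-bp identifier+tag region (the amplification arms carry the
PCR priming sites and never enter the counting logic).

This module holds the declarative schema for that layout, validation of
its arithmetic, oligo assembly, and counting-tag generation.  All
coordinates are 0-based, half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DNA_BASES",
    "DEFAULT_COUNTING_PATTERN",
    "ProteinIdentifier",
    "CountingTagPattern",
    "BarcodeSchema",
    "ValidationReport",
    "validate_schema",
    "assemble_oligo",
    "random_counting_tag",
    "draw_counting_tags",
    "generate_identifiers",
    "hamming",
    "load_schema",
    "save_schema",
]

DNA_BASES = "ACGT"
_BASE_SET = frozenset(DNA_BASES)
ROLES = ("assay", "control", "unused")

#: Default counting-tag mask: one fixed base after every four random bases.
#: Fixed bases in order are A, C, T, G, A, C (positions 4, 9, 14, 19, 24, 29).
DEFAULT_COUNTING_PATTERN = "NNNNANNNNCNNNNTNNNNGNNNNANNNNC"

# Default 31-bp amplification arms (Illumina adapter-anchored placeholders;
# arms carry priming sites only and are overridable in the schema config).
DEFAULT_ARM5 = "ACACGACGCTCTTCCGATCTGTGACTGGAGT"
DEFAULT_ARM3 = "AGATCGGAAGAGCACACGTCTGAACTCCAGT"


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ProteinIdentifier:
    """One row of the protein-identifier table.

    ``role`` distinguishes proteins measured in the assay (``assay``),
    negative controls such as barcoded HaloTag-only protein (``control``),
    and barcodes not present in the experiment at all (``unused``) — the
    latter define the sequencing background-noise reference set.
    """

    tag: str
    protein_name: str
    role: str = "assay"

    def __post_init__(self) -> None:
        if not self.tag or set(self.tag) - _BASE_SET:
            raise ValueError(f"identifier tag must be non-empty A/C/G/T: {self.tag!r}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class CountingTagPattern:
    """Mask for the semi-random counting tag.

    ``pattern`` is a string over {A,C,G,T,N}; ``N`` marks a random base,
    anything else is a fixed base that every faithful read must carry.
    """

    pattern: str = DEFAULT_COUNTING_PATTERN

    def __post_init__(self) -> None:
        bad = set(self.pattern) - (_BASE_SET | {"N"})
        if bad:
            raise ValueError(f"pattern may contain only A/C/G/T/N, found {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c != "N")

    @property
    def fixed_bases(self) -> tuple[str, ...]:
        return tuple(c for c in self.pattern if c != "N")

    @property
    def random_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c == "N")

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_positions)

    @property
    def n_random(self) -> int:
        return self.length - self.n_fixed

    def count_fixed_mismatches(self, tag: str) -> int:
        """Number of fixed positions where ``tag`` disagrees with the mask."""
        if len(tag) != self.length:
            raise ValueError(
                f"tag length {len(tag)} != pattern length {self.length}"
            )
        return sum(tag[i] != self.pattern[i] for i in self.fixed_positions)

    def matches(self, tag: str) -> bool:
        return self.count_fixed_mismatches(tag) == 0


@dataclass(frozen=True)
class BarcodeSchema:
    """Full declarative layout of the barcode oligo and identifier table."""

    identifiers: tuple[ProteinIdentifier, ...] = ()
    id_length: int = 8
    tag_length: int = 30
    amp_arm_length: int = 31
    amp_arm_count: int = 2
    arm5: str = DEFAULT_ARM5
    arm3: str = DEFAULT_ARM3
    counting_pattern: CountingTagPattern = field(default_factory=CountingTagPattern)
    #: 0-based offset of the identifier+tag region within the sequencing read.
    read_offset: int = 0
    #: design-validation floor on pairwise identifier Hamming distance
    min_identifier_distance: int = 3

    def __post_init__(self) -> None:
        if isinstance(self.identifiers, list):
            object.__setattr__(self, "identifiers", tuple(self.identifiers))

    @property
    def region_length(self) -> int:
        """Length of the extracted identifier+tag region (default 38)."""
        return self.id_length + self.tag_length

    @property
    def oligo_length(self) -> int:
        """Total barcode oligo length (default 8 + 30 + 2x31 = 100)."""
        return self.region_length + self.amp_arm_count * self.amp_arm_length

    @property
    def identifier_by_tag(self) -> dict[str, ProteinIdentifier]:
        return {ident.tag: ident for ident in self.identifiers}

    @property
    def identifier_by_name(self) -> dict[str, ProteinIdentifier]:
        return {ident.protein_name: ident for ident in self.identifiers}

    def by_role(self, role: str) -> tuple[ProteinIdentifier, ...]:
        return tuple(i for i in self.identifiers if i.role == role)

    def with_identifiers(self, identifiers: Iterable[ProteinIdentifier]) -> "BarcodeSchema":
        return replace(self, identifiers=tuple(identifiers))


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_schema`: empty ``violations`` means valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthiness == validity
        return self.ok


def validate_schema(schema: BarcodeSchema) -> ValidationReport:
    """Check every structural invariant of a schema; report all violations.

    Side-effect free and idempotent; callers decide whether to abort.
    """
    v: list[str] = []
    if schema.id_length <= 0 or schema.tag_length <= 0:
        v.append("id_length and tag_length must be positive")
    if schema.amp_arm_length < 0 or schema.amp_arm_count < 0:
        v.append("amplification arm dimensions must be non-negative")
    if len(schema.arm5) != schema.amp_arm_length:
        v.append(
            f"arm5 length {len(schema.arm5)} != amp_arm_length {schema.amp_arm_length}"
        )
    if len(schema.arm3) != schema.amp_arm_length:
        v.append(
            f"arm3 length {len(schema.arm3)} != amp_arm_length {schema.amp_arm_length}"
        )
    for arm_name, arm in (("arm5", schema.arm5), ("arm3", schema.arm3)):
        if set(arm) - _BASE_SET:
            v.append(f"{arm_name} contains non-ACGT characters")
    if schema.counting_pattern.length != schema.tag_length:
        v.append(
            f"counting pattern length {schema.counting_pattern.length} != "
            f"tag_length {schema.tag_length}"
        )
    if schema.read_offset < 0:
        v.append("read_offset must be non-negative")

    # identifier table
    tags = [i.tag for i in schema.identifiers]
    for ident in schema.identifiers:
        if len(ident.tag) != schema.id_length:
            v.append(
                f"identifier {ident.protein_name}: tag length {len(ident.tag)} "
                f"!= id_length {schema.id_length}"
            )
    dup_tags = {t for t in tags if tags.count(t) > 1}
    if dup_tags:
        v.append(f"duplicate identifier tag(s): {sorted(dup_tags)}")
    names = [i.protein_name for i in schema.identifiers]
    dup_names = {n for n in names if names.count(n) > 1}
    if dup_names:
        v.append(f"duplicate protein name(s): {sorted(dup_names)}")
    for a, b in itertools.combinations(schema.identifiers, 2):
        if len(a.tag) == len(b.tag):
            d = hamming(a.tag, b.tag)
            if d < schema.min_identifier_distance:
                v.append(
                    f"identifiers {a.protein_name}/{b.protein_name} at Hamming "
                    f"distance {d} < design minimum {schema.min_identifier_distance}"
                )
    return ValidationReport(v)


def assemble_oligo(schema: BarcodeSchema, identifier: ProteinIdentifier, tag: str) -> str:
    """Assemble the full barcode oligo: arm5 + identifier + counting tag + arm3.

    The counting tag must match the schema's pattern exactly at every fixed
    position and contain only A/C/G/T.
    """
    if set(tag) - _BASE_SET:
        raise ValueError(f"counting tag contains non-ACGT characters: {tag!r}")
    if len(tag) != schema.tag_length:
        raise ValueError(f"counting tag length {len(tag)} != {schema.tag_length}")
    mm = schema.counting_pattern.count_fixed_mismatches(tag)
    if mm:
        raise ValueError(f"counting tag violates {mm} fixed position(s): {tag}")
    if len(identifier.tag) != schema.id_length:
        raise ValueError("identifier length does not match schema id_length")
    return schema.arm5 + identifier.tag + tag + schema.arm3


def _as_rng(rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def random_counting_tag(
    pattern: CountingTagPattern, rng: int | np.random.Generator
) -> str:
    """Draw one counting tag: N positions uniform over A/C/G/T, fixed set exactly.

    Deterministic given a seed (or the state of a passed Generator).
    """
    gen = _as_rng(rng)
    chars = list(pattern.pattern)
    draws = gen.integers(0, 4, size=pattern.n_random)
    for pos, d in zip(pattern.random_positions, draws):
        chars[pos] = DNA_BASES[d]
    return "".join(chars)


def draw_counting_tags(
    pattern: CountingTagPattern,
    n: int,
    rng: int | np.random.Generator,
    unique: bool = True,
) -> list[str]:
    """Draw ``n`` counting tags; with ``unique`` collisions are re-drawn.

    The random-base space is 4**n_random (~2.8e14 for the default 24),
    so re-draws are astronomically rare at realistic n but guarantee a
    collision-free truth set by construction.
    """
    gen = _as_rng(rng)
    tags: list[str] = []
    seen: set[str] = set()
    while len(tags) < n:
        t = random_counting_tag(pattern, gen)
        if unique and t in seen:
            continue
        seen.add(t)
        tags.append(t)
    return tags


def generate_identifiers(
    n: int,
    rng: int | np.random.Generator,
    id_length: int = 8,
    min_distance: int = 3,
    names: Sequence[str] | None = None,
    roles: Sequence[str] | None = None,
    max_attempts: int = 100_000,
) -> tuple[ProteinIdentifier, ...]:
    """Sample ``n`` identifier tags with pairwise Hamming distance >= min_distance.

    Greedy rejection sampling; with 8-mers and distance 3 the space holds
    far more than the tens of identifiers a real panel uses.
    """
    gen = _as_rng(rng)
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} identifiers at distance {min_distance}"
            )
        cand = "".join(DNA_BASES[d] for d in gen.integers(0, 4, size=id_length))
        if all(hamming(cand, t) >= min_distance for t in chosen):
            chosen.append(cand)
    out = []
    for i, tag in enumerate(chosen):
        name = names[i] if names is not None else f"protein_{i:02d}"
        role = roles[i] if roles is not None else "assay"
        out.append(ProteinIdentifier(tag=tag, protein_name=name, role=role))
    return tuple(out)


# ---------------------------------------------------------------------------
# plain-text schema config (YAML; identifier table inline or as TSV sidecar)

def load_schema(path: str | Path) -> BarcodeSchema:
    """Load a schema from a YAML config.

    Identifiers may be given inline under ``identifiers`` (list of
    ``{tag, name, role}`` mappings) or in a TSV referenced by
    ``identifier_table`` with columns tag<TAB>name<TAB>role.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    idents: list[ProteinIdentifier] = []
    if "identifier_table" in cfg:
        table = path.parent / cfg.pop("identifier_table")
        with open(table) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                tag, name, role = line.split("\t")[:3]
                idents.append(ProteinIdentifier(tag=tag, protein_name=name, role=role))
    for row in cfg.pop("identifiers", []) or []:
        idents.append(
            ProteinIdentifier(
                tag=row["tag"],
                protein_name=row.get("name", row.get("protein_name", row["tag"])),
                role=row.get("role", "assay"),
            )
        )
    pattern = CountingTagPattern(cfg.pop("counting_pattern", DEFAULT_COUNTING_PATTERN))
    allowed = {
        "id_length", "tag_length", "amp_arm_length", "amp_arm_count",
        "arm5", "arm3", "read_offset", "min_identifier_distance",
    }
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown schema config keys: {sorted(unknown)}")
    return BarcodeSchema(identifiers=tuple(idents), counting_pattern=pattern, **cfg)


def save_schema(schema: BarcodeSchema, path: str | Path) -> None:
    """Serialize a schema (identifier table inline) to YAML."""
    cfg = {
        "id_length": schema.id_length,
        "tag_length": schema.tag_length,
        "amp_arm_length": schema.amp_arm_length,
        "amp_arm_count": schema.amp_arm_count,
        "arm5": schema.arm5,
        "arm3": schema.arm3,
        "counting_pattern": schema.counting_pattern.pattern,
        "read_offset": schema.read_offset,
        "min_identifier_distance": schema.min_identifier_distance,
        "identifiers": [
            {"tag": i.tag, "name": i.protein_name, "role": i.role}
            for i in schema.identifiers
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
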