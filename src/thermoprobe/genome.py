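"""Comparative-genomics summaries: MEROPS peptidase repertoires and KEGG modules.

Filtering of BLAST tabular hits against a MEROPS-style peptidase database,
per-genome family tabulation, cross-genome set algebra (shared/unique families
and the full Venn partition), percentile ranking against a reference
distribution, genome annotation-statistic percentages, and evaluation of KEGG
module definitions as module completion ratios (MCR) with the Q-value
feasibility rule.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

# --------------------------------------------------------------------------
# MEROPS hits
# --------------------------------------------------------------------------

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: Default pattern pulling the MEROPS family code off the subject-id suffix,
#: e.g. "MER0001234_S01C" -> "S01C".
DEFAULT_FAMILY_REGEX = r"([A-Z]\d+[A-Z]?)$"


@dataclass(frozen=True)
class MeropsHit:
    query_gene: str
    family: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")


def read_blast_tab(
    source: str | io.TextIOBase, family_regex: str = DEFAULT_FAMILY_REGEX
) -> list[MeropsHit]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``) into hits.

    The MEROPS family is extracted from the subject id with ``family_regex``.
    Malformed rows raise with their line number.
    """
    if isinstance(source, str):
        handle: io.TextIOBase = open(source)
        close = True
    else:
        handle, close = source, False
    pattern = re.compile(family_regex)
    hits: list[MeropsHit] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST6_COLUMNS):
                raise ValueError(
                    f"line {lineno}: expected {len(BLAST6_COLUMNS)} tab-separated "
                    f"columns, found {len(fields)}"
                )
            m = pattern.search(fields[1])
            if m is None:
                raise ValueError(
                    f"line {lineno}: cannot extract family from subject id {fields[1]!r}"
                )
            try:
                e_value = float(fields[10])
                bit_score = float(fields[11])
            except ValueError as err:
                raise ValueError(f"line {lineno}: {err}") from None
            hits.append(MeropsHit(fields[0], m.group(1), e_value, bit_score))
    finally:
        if close:
            handle.close()
    return hits


def filter_merops_hits(
    hits: Sequence[MeropsHit], e_max: float = 1e-10, best_only: bool = True
) -> list[MeropsHit]:
    """Apply the E-value cutoff and (optionally) keep one best hit per query.

    The best hit is the highest bit score; ties break by smallest E-value,
    then lexicographically smallest family code, for determinism.
    """
    kept = [h for h in hits if h.e_value <= e_max]
    if not best_only:
        return kept
    best: dict[str, MeropsHit] = {}
    for h in kept:
        prev = best.get(h.query_gene)
        if prev is None or (-h.bit_score, h.e_value, h.family) < (
            -prev.bit_score, prev.e_value, prev.family
        ):
            best[h.query_gene] = h
    return [best[q] for q in sorted(best)]


# --------------------------------------------------------------------------
# Family profiles and set algebra
# --------------------------------------------------------------------------

SECRETED_LOCALITIES = frozenset({"membrane", "extracellular", "lipoprotein"})


@dataclass
class FamilyProfile:
    """Per-genome MEROPS family -> gene-count map."""

    genome_id: str
    counts: dict[str, int]
    total_genes: int
    secreted_counts: dict[str, int] = field(default_factory=dict)

    @property
    def families_present(self) -> frozenset[str]:
        """Families represented by at least one gene."""
        return frozenset(f for f, c in self.counts.items() if c >= 1)

    @property
    def peptidase_gene_count(self) -> int:
        return sum(self.counts.values())

    def clan_totals(self) -> dict[str, int]:
        """Totals by catalytic type (leading letter of the family code)."""
        out: dict[str, int] = {}
        for fam, c in self.counts.items():
            out[fam[0]] = out.get(fam[0], 0) + c
        return out


def tabulate_families(
    annotations: pd.DataFrame | Sequence[MeropsHit],
    total_genes: int,
    genome_id: str = "genome",
    include_families: Iterable[str] = (),
) -> FamilyProfile:
    """Count genes per peptidase family for one genome.

    Accepts either filtered :class:`MeropsHit` records or an annotation table
    with columns ``gene_id``, ``family`` and optionally ``locality``; an empty
    family string marks an unannotated gene. Duplicate gene ids (which the
    best-only filter should have removed) are an error. ``include_families``
    forces zero-count entries for families absent from the input.
    """
    if isinstance(annotations, pd.DataFrame):
        df = annotations
        gene_ids = df["gene_id"].tolist()
        families = ["" if pd.isna(f) else str(f) for f in df["family"]]
        localities = (
            [str(x) for x in df["locality"]]
            if "locality" in df.columns
            else [""] * len(df)
        )
    else:
        gene_ids = [h.query_gene for h in annotations]
        families = [h.family for h in annotations]
        localities = [""] * len(gene_ids)

    seen: set[str] = set()
    counts: dict[str, int] = {f: 0 for f in include_families}
    secreted: dict[str, int] = {}
    for gid, fam, loc in zip(gene_ids, families, localities):
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r}")
        seen.add(gid)
        if not fam:
            continue
        counts[fam] = counts.get(fam, 0) + 1
        if loc in SECRETED_LOCALITIES:
            secreted[fam] = secreted.get(fam, 0) + 1
    profile = FamilyProfile(genome_id, counts, total_genes, secreted)
    if profile.peptidase_gene_count > total_genes:
        raise ValueError("more annotated peptidase genes than total genes")
    return profile


def _round_half_up(x: float, places: int = 2) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def peptidase_percentage(peptidase_count: int, total_genes: int) -> float:
    """Percentage of genes in peptidase families, rounded half-up to 2 dp."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    if peptidase_count < 0:
        raise ValueError("count must be non-negative")
    return _round_half_up(100.0 * peptidase_count / total_genes)


def shared_families(profiles: Sequence[FamilyProfile]) -> dict:
    """Set algebra over family presence (count >= 1) across genomes.

    Returns a report with the intersection and union of families, per-genome
    unique families, pairwise shared counts, and the full Venn partition: one
    disjoint cell per non-empty genome subset, keyed by the sorted tuple of
    genome ids whose profiles (and no others) contain the family.
    """
    if len(profiles) < 2:
        raise ValueError("at least two profiles are required")
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("genome ids must be unique")
    present = {p.genome_id: p.families_present for p in profiles}
    union = frozenset().union(*present.values())
    intersection = frozenset.intersection(*present.values())
    unique = {
        g: frozenset(
            f for f in present[g]
            if all(f not in present[h] for h in ids if h != g)
        )
        for g in ids
    }
    pairwise = {
        (a, b): len(present[a] & present[b]) for a, b in combinations(sorted(ids), 2)
    }
    venn: dict[tuple[str, ...], frozenset[str]] = {}
    for r in range(1, len(ids) + 1):
        for members in combinations(sorted(ids), r):
            inside = frozenset.intersection(*(present[g] for g in members))
            outside = frozenset().union(
                *(present[g] for g in ids if g not in members), frozenset()
            )
            cell = inside - outside
            if cell:
                venn[members] = cell
    return {
        "union": union,
        "intersection": intersection,
        "unique": unique,
        "pairwise_shared": pairwise,
        "venn": venn,
    }


def percentile_rank(value: float, reference_values: Sequence[float]) -> float:
    """Top-percent rank: 100 * |{r : r >= value}| / N."""
    if len(reference_values) == 0:
        raise ValueError("reference values must be non-empty")
    n_ge = sum(1 for r in reference_values if r >= value)
    return 100.0 * n_ge / len(reference_values)


# --------------------------------------------------------------------------
# Genome annotation statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeStats:
    """Genome-level annotation counts with derived percentages (2 dp)."""

    genome_size_bp: int
    coding_bp: int
    gc_bp: int
    total_genes: int
    protein_coding_genes: int
    coding_pct: float
    gc_pct: float
    protein_coding_pct: float


def annotation_stats(
    genome_size_bp: int,
    coding_bp: int,
    gc_bp: int,
    total_genes: int,
    protein_coding_genes: int,
) -> GenomeStats:
    """Derive the standard genome-table percentages from raw counts.

    Base-pair percentages use the genome size as denominator; gene
    percentages use the total gene count. All rounded half-up to 2 dp.
    """
    if genome_size_bp <= 0 or total_genes <= 0:
        raise ValueError("genome size and total genes must be positive")
    for part, whole, name in [
        (coding_bp, genome_size_bp, "coding bp"),
        (gc_bp, genome_size_bp, "G+C bp"),
        (protein_coding_genes, total_genes, "protein-coding genes"),
    ]:
        if part < 0:
            raise ValueError(f"{name} must be non-negative")
        if part > whole:
            raise ValueError(f"{name} ({part}) exceeds its denominator ({whole})")
    return GenomeStats(
        genome_size_bp=genome_size_bp,
        coding_bp=coding_bp,
        gc_bp=gc_bp,
        total_genes=total_genes,
        protein_coding_genes=protein_coding_genes,
        coding_pct=_round_half_up(100.0 * coding_bp / genome_size_bp),
        gc_pct=_round_half_up(100.0 * gc_bp / genome_size_bp),
        protein_coding_pct=_round_half_up(100.0 * protein_coding_genes / total_genes),
    )


# --------------------------------------------------------------------------
# KEGG module definitions and completion ratios
# --------------------------------------------------------------------------
#
# Definition grammar (the subset used by ordinary metabolic modules):
#   space   : AND, separating ordered steps at the top level (and sub-units
#             inside parentheses)
#   comma   : OR between alternatives
#   +       : complex subunit, all members required
#   -       : optional member, ignored for completion
#   ( ... ) : grouping
#   --      : a reaction step with no KO assigned; counts as unsatisfied
#
# Expressions are parsed into a small node tree: ("ko", id), ("and", [...]),
# ("or", [...]), ("optional", node), ("gap",).

Node = tuple


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    definition: str
    steps: tuple[Node, ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class McrResult:
    module_id: str
    mcr: float
    q_value: float | None = None
    feasible: bool | None = None


class ModuleParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == " ":
            # collapse runs of spaces into one separator
            if tokens and tokens[-1][0] != " ":
                tokens.append((" ", i))
            i += 1
        elif c in "(),+":
            tokens.append((c, i))
            i += 1
        elif c == "-":
            if text[i : i + 2] == "--":
                tokens.append(("--", i))
                i += 2
            else:
                tokens.append(("-", i))
                i += 1
        else:
            j = i
            while j < n and text[j] not in " (),+-":
                j += 1
            tokens.append((text[i:j], i))
            i = j
    return tokens


class _Parser:
    """Recursive-descent parser for one step expression (no top-level spaces)."""

    def __init__(self, tokens: list[tuple[str, int]], end_pos: int):
        self.tokens = tokens
        self.pos = 0
        self.end_pos = end_pos

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def here(self) -> int:
        return self.tokens[self.pos][1] if self.pos < len(self.tokens) else self.end_pos

    def take(self) -> tuple[str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse_expr(self) -> Node:
        """expr := seq (',' seq)*  -- OR of alternatives."""
        alts = [self.parse_seq()]
        while self.peek() == ",":
            self.take()
            alts.append(self.parse_seq())
        return alts[0] if len(alts) == 1 else ("or", alts)

    def parse_seq(self) -> Node:
        """seq := complex (' ' complex)* -- AND of space-separated sub-units."""
        parts = [self.parse_complex()]
        while self.peek() == " ":
            self.take()
            parts.append(self.parse_complex())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def parse_complex(self) -> Node:
        """complex := unit (('+'|'-') unit)* -- subunit chains."""
        parts = [self.parse_unit()]
        while self.peek() in ("+", "-"):
            op, _ = self.take()
            unit = self.parse_unit()
            parts.append(("optional", unit) if op == "-" else unit)
        return parts[0] if len(parts) == 1 else ("and", parts)

    def parse_unit(self) -> Node:
        tok = self.peek()
        pos = self.here()
        if tok is None:
            raise ModuleParseError("unexpected end of definition", pos)
        if tok == "-":
            # leading '-': the whole unit is optional
            self.take()
            return ("optional", self.parse_unit())
        if tok == "(":
            self.take()
            inner = self.parse_expr()
            if self.peek() != ")":
                raise ModuleParseError("unbalanced parenthesis", pos)
            self.take()
            return inner
        if tok == "--":
            self.take()
            return ("gap",)
        if tok in (")", ",", "+", "-", " "):
            raise ModuleParseError(f"unexpected {tok!r}", pos)
        self.take()
        return ("ko", tok)


def _split_steps(text: str) -> list[tuple[list[tuple[str, int]], int]]:
    tokens = _tokenize(text)
    steps: list[list[tuple[str, int]]] = [[]]
    depth = 0
    for tok, pos in tokens:
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise ModuleParseError("unbalanced parenthesis", pos)
        if tok == " " and depth == 0:
            steps.append([])
        else:
            steps[-1].append((tok, pos))
    if depth != 0:
        raise ModuleParseError("unbalanced parenthesis", len(text))
    return [(s, s[-1][1] if s else 0) for s in steps]


def parse_module_definition(definition: str, module_id: str = "") -> ModuleDefinition:
    """Parse a KEGG module definition string into ordered steps."""
    text = definition.strip()
    if not text:
        raise ModuleParseError("empty definition", 0)
    step_nodes: list[Node] = []
    for token_list, end_pos in _split_steps(text):
        if not token_list:
            raise ModuleParseError("empty step", end_pos)
        # a step that is exactly inside parentheses keeps internal spaces as AND
        parser = _Parser(token_list, end_pos)
        node = parser.parse_expr()
        if parser.peek() is not None:
            raise ModuleParseError(
                f"unexpected {parser.peek()!r}", parser.here()
            )
        if node[0] == "optional":
            # a wholly optional step does not count toward completion
            continue
        step_nodes.append(node)
    if not step_nodes:
        raise ModuleParseError("definition has no countable steps", 0)
    return ModuleDefinition(module_id, text, tuple(step_nodes))


def _satisfied(node: Node, kos: frozenset[str] | set[str]) -> bool:
    kind = node[0]
    if kind == "ko":
        return node[1] in kos
    if kind == "and":
        return all(_satisfied(c, kos) for c in node[1])
    if kind == "or":
        return any(_satisfied(c, kos) for c in node[1])
    if kind == "optional":
        return True
    if kind == "gap":
        return False
    raise ValueError(f"unknown node kind {kind!r}")


def step_satisfied(step: Node, kos: Iterable[str]) -> bool:
    """True if the KO set satisfies one step expression."""
    return _satisfied(step, frozenset(kos))


def module_kos(module: ModuleDefinition) -> frozenset[str]:
    """All KO identifiers appearing in a module definition."""

    def walk(node: Node) -> Iterable[str]:
        if node[0] == "ko":
            yield node[1]
        elif node[0] in ("and", "or"):
            for c in node[1]:
                yield from walk(c)
        elif node[0] == "optional":
            yield from walk(node[1])

    out: set[str] = set()
    for s in module.steps:
        out.update(walk(s))
    return frozenset(out)


def module_completion_ratio(
    module: ModuleDefinition, kos: Iterable[str]
) -> McrResult:
    """MCR = satisfied steps / total steps, from KO presence alone."""
    ko_set = frozenset(kos)
    n_sat = sum(_satisfied(s, ko_set) for s in module.steps)
    return McrResult(module.module_id, n_sat / module.n_steps)


def feasibility_call(mcr_result: McrResult, q_value: float | None) -> McrResult:
    """Attach the Q-value feasibility rule: feasible iff Q < 0.5 (strict).

    A missing Q-value leaves feasibility unknown (None).
    """
    if q_value is None:
        return McrResult(mcr_result.module_id, mcr_result.mcr, None, None)
    if not 0.0 <= q_value <= 1.0:
        raise ValueError(f"Q-value must be in [0, 1]; got {q_value}")
    return McrResult(mcr_result.module_id, mcr_result.mcr, q_value, q_value < 0.5)
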