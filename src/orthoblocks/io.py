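"""Plain-text input/output.

Two small TSV grammars (UTF-8, Unix newlines, ``#`` starts a comment line,
tokens match ``[A-Za-z0-9_.-]+``):

reference operon file — first non-comment line::

    <operon_name>\t<gene1>,<gene2>,...

candidate blocks file — one line per genome::

    <genome_id>\t<block>|<block>|...

where each block is a comma-separated list of gene occurrences; a gene
repeated within a block encodes multiplicity (``a,b,b`` means λ(b) = 2) and
an empty field after the tab encodes an empty orthoblock.  Genes absent
from the reference gene universe are rejected unless ``drop_unknown=True``
downgrades them to a warning and filters them out.

Solution reports are written as TSV or JSON with a fixed column order; all
numbers are integers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from .model import GeneBlock, Orthoblock, ReferenceOperon

logger = logging.getLogger("orthoblocks")

REPORT_COLUMNS = (
    "genome_id",
    "solver",
    "selected_blocks",
    "deletion",
    "split",
    "duplication",
    "total",
    "objective_f",
)


def format_block(block: GeneBlock) -> str:
    return ",".join(block.display_order)


def format_orthoblock(o: Orthoblock) -> str:
    return "|".join(format_block(b) for b in o.blocks)


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    return out


def read_reference(path: str | Path) -> ReferenceOperon:
    """Parse a reference operon file (first non-comment line)."""
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: no reference operon line found")
    lineno, line = lines[0]
    if "\t" not in line:
        raise ValueError(f"{path}:{lineno}: expected '<name>\\t<gene1>,<gene2>,...'")
    name, genes_field = line.split("\t", 1)
    genes = [g for g in genes_field.strip().split(",") if g != ""]
    if not genes:
        raise ValueError(f"{path}:{lineno}: reference operon {name!r} lists no genes")
    return ReferenceOperon(name=name.strip(), genes=tuple(genes))


def _parse_block(
    field: str,
    reference: ReferenceOperon,
    drop_unknown: bool,
    where: str,
) -> GeneBlock | None:
    occurrences = field.split(",")
    if any(g == "" for g in occurrences):
        raise ValueError(f"{where}: empty gene token in block {field!r}")
    universe = reference.gene_set()
    unknown = sorted({g for g in occurrences if g not in universe})
    if unknown:
        if not drop_unknown:
            raise ValueError(
                f"{where}: genes not in reference operon {reference.name!r}: "
                f"{', '.join(unknown)} (use drop_unknown to filter them)"
            )
        logger.warning("%s: dropping genes not in the reference universe: %s",
                       where, ", ".join(unknown))
        occurrences = [g for g in occurrences if g in universe]
        if not occurrences:
            return None
    return GeneBlock(occurrences)


def read_blocks(
    path: str | Path,
    reference: ReferenceOperon,
    drop_unknown: bool = False,
) -> dict[str, Orthoblock]:
    """Parse a candidate blocks file into genome_id → Orthoblock (input order kept)."""
    genomes: dict[str, Orthoblock] = {}
    for lineno, line in _data_lines(path):
        where = f"{path}:{lineno}"
        if "\t" not in line:
            raise ValueError(f"{where}: expected '<genome_id>\\t<block>|<block>|...'")
        genome_id, blocks_field = line.split("\t", 1)
        genome_id = genome_id.strip()
        if genome_id in genomes:
            raise ValueError(f"{where}: duplicate genome id {genome_id!r}")
        blocks: list[GeneBlock] = []
        if blocks_field.strip():
            for part in blocks_field.strip().split("|"):
                if part == "":
                    raise ValueError(f"{where}: empty block between '|' separators")
                b = _parse_block(part, reference, drop_unknown, where)
                if b is not None:
                    blocks.append(b)
        genomes[genome_id] = Orthoblock(genome_id=genome_id, blocks=blocks)
    return genomes


def write_reference(reference: ReferenceOperon, path: str | Path) -> None:
    Path(path).write_text(
        f"# reference operon: {reference.name}\n"
        f"{reference.name}\t{','.join(reference.genes)}\n",
        encoding="utf-8",
    )


def write_blocks(genomes: dict[str, Orthoblock], path: str | Path) -> None:
    lines = [f"{gid}\t{format_orthoblock(o)}" for gid, o in genomes.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class SolutionRecord:
    """One report row: a genome's selected orthoblock and its event costs."""

    genome_id: str
    solver: str
    selected_blocks: str
    deletion: int
    split: int
    duplication: int
    total: int
    objective_f: int

    def __post_init__(self):
        for name in ("deletion", "split", "duplication", "total", "objective_f"):
            v = getattr(self, name)
            if not isinstance(v, int):
                raise ValueError(f"{name} must be an integer, got {v!r}")


def write_report(
    records: list[SolutionRecord], path: str | Path, format: str = "tsv"
) -> None:
    """Write solution records, preserving input row order.

    ``format`` is ``tsv`` (header + one row per record) or ``json`` (a list
    of objects with the same fields).
    """
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for rec in records:
            d = asdict(rec)
            lines.append("\t".join(str(d[col]) for col in REPORT_COLUMNS))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        payload = [{col: getattr(rec, col) for col in REPORT_COLUMNS} for rec in records]
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}: expected tsv or json")


def read_report(path: str | Path, format: str = "tsv") -> list[SolutionRecord]:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    records: list[SolutionRecord] = []
    if format == "tsv":
        lines = path.read_text(encoding="utf-8").splitlines()
        if not lines or tuple(lines[0].split("\t")) != REPORT_COLUMNS:
            raise ValueError(f"{path}: missing or malformed report header")
        for line in lines[1:]:
            fields = dict(zip(REPORT_COLUMNS, line.split("\t")))
            records.append(
                SolutionRecord(
                    genome_id=fields["genome_id"],
                    solver=fields["solver"],
                    selected_blocks=fields["selected_blocks"],
                    deletion=int(fields["deletion"]),
                    split=int(fields["split"]),
                    duplication=int(fields["duplication"]),
                    total=int(fields["total"]),
                    objective_f=int(fields["objective_f"]),
                )
            )
    elif format == "json":
        for obj in json.loads(path.read_text(encoding="utf-8")):
            records.append(SolutionRecord(**obj))
    else:
        raise ValueError(f"unknown report format {format!r}: expected tsv or json")
    return records
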