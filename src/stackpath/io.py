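"""Instance readers and report writers.

An *instance* is one RNA sequence plus a start structure A and an end
structure B in dot-bracket notation.  The native on-disk form is a
3-line plain-text file (sequence / A / B; blank lines and ``#`` or
``>`` header lines are ignored).  A FASTA sequence plus a 2-line
structure file is also accepted.  Reports are a plain-text pathway
table, a JSON run report and a CSV per-generation trace; all positions
are 1-based and energies are printed to 0.01 kcal/mol.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

from .pathway import Action, ActionChain, PathwayRecord, validate_chain
from .structure import (
    RnaSequence,
    SecondaryStructure,
    pair_allowed,
    parse_structure,
    render_structure,
)

__all__ = [
    "Instance",
    "read_instance",
    "read_fasta_sequence",
    "write_reports",
    "read_report",
    "format_pathway_table",
]


@dataclass(frozen=True)
class Instance:
    """An RNA sequence with its start and end secondary structures."""

    x: RnaSequence
    A: SecondaryStructure
    B: SecondaryStructure
    label: str = "instance"

    def __post_init__(self) -> None:
        n = self.x.n
        for name, S in (("A", self.A), ("B", self.B)):
            if S.max_position() > n:
                raise ValueError(
                    f"structure {name} reaches position {S.max_position()} "
                    f"but the sequence has length {n}"
                )
            for i, j in S.pairs:
                if not pair_allowed(self.x, i, j):
                    raise ValueError(
                        f"structure {name} pairs ({i},{j}) = "
                        f"{self.x.base(i)}-{self.x.base(j)}, which is not an "
                        "admissible pair for this sequence"
                    )


def _content_lines(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith(">"):
            continue
        out.append(line)
    return out


def read_instance(path: str | Path, label: str | None = None) -> Instance:
    """Read a 3-line instance file (sequence, structure A, structure B)."""
    path = Path(path)
    lines = _content_lines(path.read_text())
    if len(lines) < 3:
        raise ValueError(
            f"{path}: expected sequence and two dot-bracket lines, "
            f"found {len(lines)} content line(s)"
        )
    x = RnaSequence(lines[0])
    A = parse_structure(lines[1])
    B = parse_structure(lines[2])
    for which, s in (("A", lines[1]), ("B", lines[2])):
        if len(s) != x.n:
            raise ValueError(
                f"{path}: structure {which} has length {len(s)} "
                f"but the sequence has length {x.n}"
            )
    return Instance(x, A, B, label or path.stem)


def read_fasta_sequence(path: str | Path) -> RnaSequence:
    """First record of a FASTA file; extra records trigger a warning."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} FASTA records; using the first",
            stacklevel=2,
        )
    return RnaSequence(str(records[0].seq))


def format_pathway_table(
    record: PathwayRecord, x: RnaSequence
) -> str:
    """Three-column pathway table: action, dot-bracket, energy."""
    rows = ["step  action      structure" + " " * max(1, x.n - 8) + "energy"]
    structures = record.chain.intermediates()
    for t, S in enumerate(structures):
        action = str(record.chain.actions[t - 1]) if t else "-"
        rows.append(
            f"{t:>4}  {action:<10}  {render_structure(S, x.n)}  "
            f"{record.energies[t]:>7.2f}"
        )
    return "\n".join(rows) + "\n"


def write_reports(
    record: PathwayRecord,
    trace,
    cfg,
    out_dir: str | Path,
    instance: Instance,
) -> dict[str, Path]:
    """Write pathway table, JSON run report and CSV trace into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = instance.x.n

    table_path = out / "pathway.txt"
    table_path.write_text(format_pathway_table(record, instance.x))

    cfg_dict = dict(cfg) if isinstance(cfg, dict) else {
        k: v for k, v in vars(cfg).items()
    }
    report = {
        "label": instance.label,
        "sequence": instance.x.letters,
        "structure_a": render_structure(instance.A, n),
        "structure_b": render_structure(instance.B, n),
        "config": cfg_dict,
        "barrier": round(record.barrier, 2),
        "saddle_index": record.saddle_index,
        "mean_excess": round(record.mean_excess, 2),
        "energies": [round(e, 2) for e in record.energies],
        "actions": [
            {"kind": a.kind, "i": a.pair[0], "j": a.pair[1]}
            for a in record.chain.actions
        ],
        "trace": [
            {
                "generation": g.generation,
                "barrier": round(g.opt_barrier, 2),
                "allocated": g.allocated,
                "selected": g.selected,
            }
            for g in trace
        ],
    }
    json_path = out / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    csv_path = out / "trace.csv"
    with csv_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["generation", "barrier"])
        for g in trace:
            writer.writerow([g.generation, f"{g.opt_barrier:.2f}"])
    return {"table": table_path, "json": json_path, "csv": csv_path}


def read_report(path: str | Path) -> dict:
    """Read back a JSON run report and re-validate its action chain."""
    data = json.loads(Path(path).read_text())
    A = parse_structure(data["structure_a"])
    B = parse_structure(data["structure_b"])
    actions = [Action(a["kind"], (a["i"], a["j"])) for a in data["actions"]]
    v = validate_chain(A, B, actions)
    if not v.ok:
        raise ValueError(
            f"{path}: stored action chain invalid at step "
            f"{v.failed_step}: {v.reason}"
        )
    data["chain"] = ActionChain(tuple(actions), A, B)
    return data
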