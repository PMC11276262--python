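"""Readers and writers for the flat-file formats the pipeline touches.

Supported inputs: STRING ``protein.links``-style interaction tables,
two-column protein→term TSVs, GAF 2.x annotation files and domain-scan
tabular reports.  The only output format is a deterministic edge-list TSV.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PPIRecord",
    "pair_key",
    "read_string_links",
    "read_annotation_table",
    "read_domain_table",
    "write_edge_list",
    "read_edge_list",
]

_VERSION_SUFFIX = re.compile(r"\.\d+$")


@dataclass(frozen=True)
class PPIRecord:
    """One (unordered) protein pair with an optional confidence score.

    ``combined_score`` is on the STRING 0-1000 integer scale; generated
    negatives carry ``None``.  ``label`` is one of ``positive``,
    ``negative``, ``unknown``.
    """

    protein_a: str
    protein_b: str
    combined_score: int | None = None
    label: str = "unknown"

    def key(self) -> tuple[str, str]:
        return pair_key(self.protein_a, self.protein_b)


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered representation of a pair."""
    return (a, b) if a <= b else (b, a)


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_string_links(
    path: str | Path,
    min_score: int = 900,
    strip_taxid_prefix: bool = False,
) -> list[PPIRecord]:
    """Read a STRING ``protein.links`` table, keeping score > ``min_score``.

    Columns are ``protein1 protein2 combined_score`` separated by whitespace
    or tabs, with an optional header row.  The score scale is auto-detected:
    if every score is <= 1 the file is taken to be on a 0-1 scale and is
    rescaled to 0-1000 integers.  The filter is strict (a record at exactly
    ``min_score`` is dropped); duplicate unordered pairs collapse to the
    maximum score.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    first_data_row = True
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}, line {lineno}: expected 3 columns, got {len(fields)}")
        a, b, raw_score = fields[0], fields[1], fields[2]
        try:
            score = float(raw_score)
        except ValueError:
            if first_data_row:
                first_data_row = False
                continue  # header row
            raise ValueError(
                f"{path}, line {lineno}: non-numeric combined_score {raw_score!r}"
            ) from None
        first_data_row = False
        if strip_taxid_prefix:
            a = a.split(".", 1)[-1]
            b = b.split(".", 1)[-1]
        rows.append((a, b, score))

    if not rows:
        warnings.warn(f"{path}: no interaction rows found", UserWarning, stacklevel=2)
        return []

    if max(score for _, _, score in rows) <= 1.0:
        rows = [(a, b, score * 1000.0) for a, b, score in rows]

    best: dict[tuple[str, str], int] = {}
    for a, b, score in rows:
        iscore = int(round(score))
        key = pair_key(a, b)
        if iscore > best.get(key, -1):
            best[key] = iscore

    return [
        PPIRecord(a, b, combined_score=score, label="positive")
        for (a, b), score in sorted(best.items())
        if score > min_score
    ]


def _looks_like_gaf(path: Path) -> bool:
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("!"):
                return True
            return len(line.split("\t")) >= 15
    return False


def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """Read a protein→term table from two-column TSV or GAF 2.x.

    For GAF, column 2 (object id) and column 5 (GO id) are used; rows whose
    qualifier contains ``NOT`` are skipped.  Duplicates collapse.
    """
    path = Path(path)
    table: dict[str, set[str]] = {}

    if _looks_like_gaf(path):
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("!"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    continue
                qualifier = fields[3]
                if "NOT" in qualifier.split("|"):
                    continue
                protein, term = fields[1], fields[4]
                if protein:
                    table.setdefault(protein, set()).add(term)
        return table

    n_rows = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}, line {lineno}: expected 2 columns, got {len(fields)}")
        protein, term = fields[0].strip(), fields[1].strip()
        if not protein:
            raise ValueError(f"{path}, line {lineno}: empty protein id")
        table.setdefault(protein, set()).add(term)
        n_rows += 1
    if n_rows == 0:
        warnings.warn(f"{path}: empty annotation table", UserWarning, stacklevel=2)
    return table


def read_domain_table(
    path: str | Path,
    protein_col: int = 0,
    domain_col: int = 5,
) -> dict[str, set[str]]:
    """Read a protein→domain table.

    Accepts either a plain two-column TSV or a whitespace-delimited
    domain-scan report (``#`` comment lines ignored; the sequence-id and
    accession column indices are configurable and default to the pfam-scan
    layout).  Version suffixes on accessions (``PF00001.12``) are stripped.
    """
    path = Path(path)
    table: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        tab_fields = line.split("\t")
        if len(tab_fields) == 2:
            protein, domain = tab_fields[0].strip(), tab_fields[1].strip()
        else:
            fields = line.split()
            if len(fields) == 2:
                protein, domain = fields
            elif len(fields) > max(protein_col, domain_col):
                protein, domain = fields[protein_col], fields[domain_col]
            else:
                raise ValueError(
                    f"{path}, line {lineno}: unrecognized domain-table dialect: {line!r}"
                )
        if not protein:
            raise ValueError(f"{path}, line {lineno}: empty protein id")
        table.setdefault(protein, set()).add(_VERSION_SUFFIX.sub("", domain))
    if not table:
        warnings.warn(f"{path}: empty domain table", UserWarning, stacklevel=2)
    return table


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

_EDGE_HEADER = "protein_a\tprotein_b\tscore"


def write_edge_list(
    edges: Iterable[tuple[str, str, float]],
    path: str | Path,
) -> None:
    """Write scored edges as TSV, sorted lexicographically by unordered pair.

    Scores must lie in [0, 1] and are rendered with six decimals so the file
    round-trips losslessly through :func:`read_edge_list`.
    """
    normalized = []
    for a, b, score in edges:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"edge score out of [0, 1]: {score!r} for ({a}, {b})")
        ka, kb = pair_key(a, b)
        normalized.append((ka, kb, round(float(score), 6)))
    normalized.sort()
    with open(path, "w") as fh:
        fh.write(_EDGE_HEADER + "\n")
        for a, b, score in normalized:
            fh.write(f"{a}\t{b}\t{score:.6f}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read an edge-list TSV written by :func:`write_edge_list`."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line == _EDGE_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}, line {lineno}: expected 3 columns")
            edges.append((fields[0], fields[1], float(fields[2])))
    return edges
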