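"""Pedigree file formats and exports.

Reads/writes the four-column pedigree contract (ind, father, mother, sex;
0 = unknown parent) as TSV or CSV with a header, plus the PLINK .fam dialect
(FID and phenotype columns ignored).  Extra columns in delimited files are
preserved as annotations.  Sub-genealogies can be exported as Graphviz DOT
with sex-shaped nodes.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .pedigree import Genealogy, PedigreeError, MALE

__all__ = ["read_pedigree", "write_pedigree", "to_dot", "write_matrix", "file_digest"]

_REQUIRED = ("ind", "father", "mother", "sex")


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".fam":
        return "fam"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_pedigree(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a pedigree table; dialect auto-detected from the extension
    (.fam / .csv / anything-else=TSV) unless given.

    Delimited files need header columns ind, father, mother, sex (common
    aliases such as id/fid/mid accepted); extra columns are carried through.
    .fam files are headerless six-column PLINK pedigrees: FID is ignored, sex
    is column 5 and the phenotype column is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise PedigreeError(f"pedigree file not found: {path}")
    dialect = dialect or _detect_dialect(path)
    if dialect == "fam":
        df = pd.read_csv(path, sep=r"\s+", header=None)
        if df.shape[1] < 5:
            raise PedigreeError(
                f".fam file must have >= 5 columns, found {df.shape[1]}"
            )
        out = pd.DataFrame(
            {
                "ind": df[1],
                "father": df[2],
                "mother": df[3],
                "sex": df[4],
            }
        )
    elif dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep)
        if df.empty:
            raise PedigreeError(f"pedigree file is empty: {path}")
        rename = {}
        lower = {c.lower(): c for c in df.columns}
        aliases = {
            "ind": ("ind", "id", "iid"),
            "father": ("father", "fid", "father_id"),
            "mother": ("mother", "mid", "mother_id"),
            "sex": ("sex",),
        }
        for canonical, names in aliases.items():
            for a in names:
                if a in lower:
                    rename[lower[a]] = canonical
                    break
            else:
                raise PedigreeError(
                    f"missing required pedigree column {canonical!r} in {path} "
                    f"(have: {list(df.columns)})"
                )
        out = df.rename(columns=rename)
        # Canonical columns first, annotations after.
        extra = [c for c in out.columns if c not in _REQUIRED]
        out = out[list(_REQUIRED) + extra]
    else:
        raise PedigreeError(f"unknown dialect {dialect!r}")
    for col in _REQUIRED:
        try:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise PedigreeError(
                f"column {col!r} in {path} is not numeric: {exc}"
            ) from exc
    return out.reset_index(drop=True)


def write_pedigree(
    table: pd.DataFrame | Genealogy, path: str | Path, dialect: str | None = None
) -> None:
    """Write a pedigree table (or a Genealogy's table) as TSV/CSV."""
    if isinstance(table, Genealogy):
        table = table.to_table()
    path = Path(path)
    dialect = dialect or _detect_dialect(path)
    sep = "," if dialect == "csv" else "\t"
    table.to_csv(path, sep=sep, index=False)


def to_dot(gen: Genealogy, name: str = "genealogy") -> str:
    """Graphviz DOT export: males as boxes, females as ellipses, edges from
    parents down to children."""
    lines = [f"digraph {name} {{", "  rankdir=TB;"]
    for i in gen.individuals:
        shape = "box" if gen.sex(i) == MALE else "ellipse"
        lines.append(f'  n{i} [label="{i}", shape={shape}];')
    for i in gen.individuals:
        for c in gen.children_of(i):
            lines.append(f"  n{i} -> n{c};")
    lines.append("}")
    return "\n".join(lines)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """TSV matrix with id header row/column; floats at 10 significant digits
    so downstream rounding is unambiguous."""
    df.to_csv(path, sep="\t", float_format="%.10g")


def file_digest(path: str | Path) -> str:
    """Short SHA-256 digest of an input file, for reproducibility logs."""
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return h[:16]
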