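"""File-format bindings: FASTA references, TSV count matrices and maps,
MaveDB-style score CSVs, YAML configs.

Count matrices are plain TSV with an ``id`` column (barcode or variant
name) and one column per sample named ``rep<r>:bin<b>`` (sort-seq) or
``rep<r>:day<d>`` (depletion time course); sample roles are recovered by
parsing the header.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .variants import ReferenceModel

_SAMPLE_RE = re.compile(r"^rep(\d+):(bin|day)(\d+)$")


def read_reference_fasta(path: str | Path) -> ReferenceModel:
    """First record of a FASTA file, interpreted as the reference CDS."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceModel.from_cds(str(record.seq))


def write_reference_fasta(ref: ReferenceModel, path: str | Path, name: str = "reference_cds") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(ref.cds), 60):
            fh.write(ref.cds[i : i + 60] + "\n")


def parse_sample_columns(columns: list[str]) -> pd.DataFrame:
    """Split ``rep<r>:bin<b>`` / ``rep<r>:day<d>`` headers into roles."""
    rows = []
    for col in columns:
        m = _SAMPLE_RE.match(col)
        if not m:
            raise ValueError(f"unrecognized sample column {col!r}")
        rows.append((col, int(m.group(1)), m.group(2), int(m.group(3))))
    return pd.DataFrame(rows, columns=["column", "replicate", "role", "index"])


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """TSV count matrix indexed by the ``id`` column; validates headers."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str}).set_index("id")
    parse_sample_columns(list(df.columns))
    if (df.values < 0).any():
        raise ValueError("negative counts in count matrix")
    return df


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="id")


def read_barcode_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"barcode": str}).set_index("barcode")


def write_barcode_map(bc_map: pd.DataFrame, path: str | Path) -> None:
    bc_map.to_csv(path, sep="\t", index_label="barcode")


def write_score_csv(scores: pd.DataFrame, path: str | Path) -> None:
    """MaveDB-style score table (``hgvs_pro`` key column)."""
    out = scores.reset_index().rename(columns={"index": "hgvs_pro", "name": "hgvs_pro"})
    out.to_csv(path, index=False)


def read_score_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("hgvs_pro")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
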