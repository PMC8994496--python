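"""Plain-text readers/writers for the pipeline's file formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import ProbeMatrix


def read_probe_matrix(
    matrix_path: str | Path,
    design_path: str | Path,
    qc_path: str | Path | None = None,
) -> ProbeMatrix:
    """Read a probe intensity TSV (probe_id, is_control, one column per
    sample), the sample design table, and an optional per-cell QC flag TSV
    (1 = pass).  Without a QC file every cell passes."""
    df = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    if "is_control" not in df.columns:
        raise ValueError("probe matrix lacks an 'is_control' column")
    is_control = df["is_control"].astype(bool)
    intensity = df.drop(columns=["is_control"]).astype(float)

    design = pd.read_csv(design_path, sep="\t", index_col="sample")
    missing = set(intensity.columns) - set(design.index)
    if missing:
        raise ValueError(
            f"sample(s) missing from design table: {', '.join(sorted(missing)[:5])}"
        )
    design = design.loc[list(intensity.columns)]

    if qc_path is not None:
        qc = pd.read_csv(qc_path, sep="\t", index_col="probe_id").astype(bool)
        qc = qc.reindex(index=intensity.index, columns=intensity.columns,
                        fill_value=True)
    else:
        qc = pd.DataFrame(True, index=intensity.index, columns=intensity.columns)
    return ProbeMatrix(intensity=intensity, is_control=is_control, qc_pass=qc,
                       design=design)


def read_probe_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "gene"} <= set(df.columns):
        raise ValueError("probe map needs columns probe_id and gene")
    return df.set_index("probe_id")["gene"]


def read_gene_list(path: str | Path) -> set[str]:
    """One gene name per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
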