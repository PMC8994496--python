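"""Probe QC filtering and two-stage median-ratio normalization.

The platform carries non-biological control probes on every array.
Normalization is ratio-based and happens in two sequential divisions:

1. every intensity on an array is divided by the median intensity of that
   array's control probes (removes the per-array multiplicative scale);
2. every probe's stage-1 value is divided by that probe's median stage-1
   value across all arrays (removes the probe-specific baseline).

Rows containing any missing value (QC failures) are then removed and the
matrix is log2-transformed.  Both divisors are kept as provenance so the
two median contracts — per-array control median of 1 after stage 1, and
per-probe cross-array median of 1 after stage 2 — can be re-checked on the
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ProbeMatrix


class PreprocessError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """Log2 normalized probe matrix plus normalization provenance.

    ``log2`` holds the final values (gene probes only unless controls were
    kept).  ``stage1`` holds the pre-log control-normalized values for all
    probes that survived QC — the surface on which the control-median
    contract holds.  ``array_control_median`` and ``probe_median`` are the
    stage-1 and stage-2 divisors.
    """

    log2: pd.DataFrame
    stage1: pd.DataFrame
    array_control_median: pd.Series
    probe_median: pd.Series
    is_control: pd.Series
    design: pd.DataFrame


def qc_filter(m: ProbeMatrix) -> ProbeMatrix:
    """Mask QC-failing cells as missing and drop all-missing probe rows."""
    if m.intensity.empty:
        raise PreprocessError("empty matrix after QC: no probes supplied")
    out = m.copy()
    out.intensity = out.intensity.where(out.qc_pass)
    keep = out.intensity.notna().any(axis=1)
    if not keep.any():
        raise PreprocessError("empty matrix after QC: every probe failed in every sample")
    out.intensity = out.intensity.loc[keep]
    out.qc_pass = out.qc_pass.loc[keep]
    out.is_control = out.is_control.loc[keep]
    return out


def normalize(m: ProbeMatrix, drop_controls: bool = True) -> NormalizedMatrix:
    """Two-stage median normalization followed by missing-row removal and log2.

    Stage-2 medians are computed on stage-1 (control-normalized) values,
    ignoring missing cells; rows still carrying a missing value after both
    divisions are removed before the log2 transform.  By default control
    probes are excluded from the returned ``log2`` matrix — they carry no
    biological signal — but the stage-1 surface retains them.
    """
    vals = m.intensity.where(m.qc_pass)
    ctrl = vals.loc[m.is_control.reindex(vals.index, fill_value=False)]
    if ctrl.empty:
        raise PreprocessError("no control probes present; cannot normalize")

    ctrl_median = ctrl.median(axis=0, skipna=True)
    dead = ctrl_median.index[ctrl_median.isna()]
    if len(dead):
        raise PreprocessError(
            f"array(s) with zero usable control probes: {', '.join(map(str, dead))}"
        )
    if (ctrl_median <= 0).any():
        bad = ctrl_median.index[ctrl_median <= 0]
        raise PreprocessError(
            f"non-positive control median on array(s): {', '.join(map(str, bad))}"
        )

    stage1 = vals.div(ctrl_median, axis=1)
    probe_median = stage1.median(axis=1, skipna=True)
    if (probe_median <= 0).any():
        bad = probe_median.index[probe_median <= 0]
        raise PreprocessError(
            f"non-positive cross-array median for probe(s): {', '.join(map(str, bad[:5]))}"
        )
    stage2 = stage1.div(probe_median, axis=0)

    complete = stage2.notna().all(axis=1)
    final = stage2.loc[complete]
    is_control = m.is_control.reindex(final.index, fill_value=False)
    if drop_controls:
        final = final.loc[~is_control]
    log2 = np.log2(final)

    return NormalizedMatrix(
        log2=log2,
        stage1=stage1,
        array_control_median=ctrl_median,
        probe_median=probe_median,
        is_control=m.is_control,
        design=m.design.copy(),
    )
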