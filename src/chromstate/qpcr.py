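"""ChIP-qPCR double-delta Cq (ddCq) fold-change math.

Input Cq values are first adjusted for the fraction of chromatin the input
aliquot represents (subtract log2(1/fraction); 3.32 cycles at 10%). Fold
change at a locus is 2^(-ddCq) where ddCq contrasts the IP and adjusted
input delta-Cq values against intergenic negative-control loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2

import pandas as pd

__all__ = [
    "CqRecord",
    "adjust_input_cq",
    "ddcq_fold_change",
    "fold_changes_from_table",
    "INPUT_ADJUSTMENT_10PCT",
]

INPUT_ADJUSTMENT_10PCT = round(log2(10), 2)  # the printed 3.32


@dataclass(frozen=True)
class CqRecord:
    locus: str
    assay: str  # "ip" or "input"
    cq: float
    input_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must lie in (0, 1]")
        if not pd.notna(self.cq):
            raise ValueError("Cq must be finite")


def adjust_input_cq(cq: float, input_fraction: float = 0.1) -> float:
    """Adjusted input Cq: subtract log2(1/fraction) cycles.

    The exact constant log2(10) = 3.3219... is used at the default 10%
    fraction; 3.32 is its display rounding.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must lie in (0, 1]")
    return cq - log2(1.0 / input_fraction)


def ddcq_fold_change(
    cq_ip: float,
    cq_input_adj: float,
    cq_intergenic_ip: float,
    cq_intergenic_input_adj: float,
) -> float:
    """Fold change 2^(-ddCq).

    dCq_IP = Cq_IP - Cq_intergenic_IP; dCq_input likewise on adjusted
    input values; ddCq = dCq_IP - dCq_input.
    """
    d_ip = cq_ip - cq_intergenic_ip
    d_input = cq_input_adj - cq_intergenic_input_adj
    return 2.0 ** (-(d_ip - d_input))


def fold_changes_from_table(
    table: pd.DataFrame,
    control_loci: list[str],
    input_fraction: float = 0.1,
) -> pd.DataFrame:
    """Per-locus ddCq fold changes from a long-format Cq table.

    ``table`` needs columns locus, assay ('ip' or 'input'), cq. The
    intergenic negative-control loci are averaged (per assay) before use;
    passing a single control locus gives single-control mode.
    """
    required = {"locus", "assay", "cq"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if not control_loci:
        raise ValueError("at least one intergenic control locus is required")
    wide = table.pivot_table(index="locus", columns="assay", values="cq")
    for col in ("ip", "input"):
        if col not in wide.columns:
            raise ValueError(f"missing assay {col!r} in table")
    missing = [c for c in control_loci if c not in wide.index]
    if missing:
        raise ValueError(f"control loci absent from table: {missing}")
    wide["input_adj"] = [adjust_input_cq(v, input_fraction) for v in wide["input"]]
    ctrl_ip = float(wide.loc[control_loci, "ip"].mean())
    ctrl_input_adj = float(wide.loc[control_loci, "input_adj"].mean())
    rows = []
    for locus, row in wide.iterrows():
        if locus in control_loci:
            continue
        d_ip = row["ip"] - ctrl_ip
        d_input = row["input_adj"] - ctrl_input_adj
        rows.append(
            {
                "locus": locus,
                "dcq_ip": d_ip,
                "dcq_input": d_input,
                "ddcq": d_ip - d_input,
                "fold_change": 2.0 ** (-(d_ip - d_input)),
            }
        )
    return pd.DataFrame(rows).set_index("locus")
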