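"""Genus relative-abundance tables and their correlation with PCB exposure.

Samples carry metadata (sample id, day, reactor, in-reactor PCB dust
concentration) plus per-genus relative abundances in percent.  Exposure can
be encoded either as the dust concentration at the sampling day (looked up
in a material-balance dilution series) or as binary presence; per-genus
Pearson product-moment correlations against the exposure vector quantify
which genera respond positively or negatively to the dust.  Genera with a
constant abundance (including all-zero) have an undefined correlation and
are flagged rather than given a number.  No multiple-testing correction is
applied; r values are reported without p-values by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dilution import DilutionSeries

__all__ = [
    "AbundanceTable",
    "ExposureVector",
    "METADATA_COLUMNS",
    "pearson_r",
    "correlate_genera",
    "encode_exposure",
]

METADATA_COLUMNS = ["sample_id", "day", "reactor", "pcb_gL"]

#: Allowed deviation of a per-sample total from 100% when "Other" is present.
TOTAL_TOL = 1.0


@dataclass
class AbundanceTable:
    """Samples x genera relative abundances (%) with sample metadata.

    ``data`` is a wide DataFrame: metadata columns (``sample_id``, ``day``,
    ``reactor``, ``pcb_gL``) plus one column per genus.  Partial tables
    (totals below 100% without an "Other" column) are accepted.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"abundance table missing metadata columns: {missing}")
        genera = self.genera
        if not genera:
            raise ValueError("abundance table has no genus columns")
        ab = self.data[genera].to_numpy(dtype=float)
        bad = np.argwhere((ab < 0) | (ab > 100))
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                f"abundance out of [0, 100]: sample row {i} "
                f"({self.data['sample_id'].iloc[i]!r}), genus {genera[j]!r}, "
                f"value {ab[i, j]}"
            )
        totals = ab.sum(axis=1)
        has_other = "Other" in genera
        for i, total in enumerate(totals):
            if total <= 0 or total > 100 + TOTAL_TOL:
                raise ValueError(
                    f"sample row {i} ({self.data['sample_id'].iloc[i]!r}) "
                    f"abundances sum to {total:.2f}%, outside (0, 100]"
                )
            if has_other and abs(total - 100) > TOTAL_TOL:
                raise ValueError(
                    f"sample row {i} ({self.data['sample_id'].iloc[i]!r}) has an "
                    f"'Other' column but sums to {total:.2f}% (must be 100 ± {TOTAL_TOL})"
                )

    @property
    def genera(self) -> list[str]:
        return [c for c in self.data.columns if c not in METADATA_COLUMNS]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def abundance(self, genus: str) -> np.ndarray:
        if genus not in self.genera:
            raise KeyError(f"unknown genus {genus!r}")
        return self.data[genus].to_numpy(dtype=float)


@dataclass
class ExposureVector:
    """Per-sample PCB exposure: dust concentration (g/L) or binary presence."""

    values: np.ndarray
    mode: str  # "concentration" | "presence"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("concentration", "presence"):
            raise ValueError(f"mode must be 'concentration' or 'presence', got {self.mode!r}")
        if np.any(self.values < 0):
            raise ValueError("exposure values must be >= 0")


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Requires n >= 3 and both vectors non-constant (a constant vector has an
    undefined correlation and raises ``ValueError``).
    """
    x = np.asarray(getattr(x, "values", x), dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 samples, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def correlate_genera(
    table: AbundanceTable, exposure: ExposureVector
) -> pd.DataFrame:
    """Per-genus Pearson correlation with the exposure vector.

    Returns a DataFrame indexed by genus with columns ``r`` (NaN when
    undefined), ``n`` and ``defined``.
    """
    if len(exposure.values) != table.n_samples:
        raise ValueError(
            f"exposure length {len(exposure.values)} != sample count {table.n_samples}"
        )
    rows = {}
    for genus in table.genera:
        y = table.abundance(genus)
        try:
            r = pearson_r(exposure.values, y)
            rows[genus] = (r, len(y), True)
        except ValueError:
            rows[genus] = (math.nan, len(y), False)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["r", "n", "defined"]
    ).rename_axis("genus")


def encode_exposure(
    table: AbundanceTable,
    dilution_series: DilutionSeries | None,
    mode: str = "concentration",
) -> ExposureVector:
    """Exposure vector for the table's samples.

    Control-reactor samples get exposure 0.  Experimental samples look up
    the dust concentration at their sampling day in ``dilution_series``
    (exact day or the most recent step value); ``mode="presence"`` then maps
    any positive concentration to 1.  A sampling day preceding the series
    raises ``KeyError``.
    """
    values = []
    for row in table.data.itertuples():
        if str(row.reactor).lower().startswith("control"):
            conc = 0.0
        else:
            if dilution_series is None:
                raise ValueError("dilution series required for non-control samples")
            conc = dilution_series.at_day(float(row.day))
        values.append(conc)
    values = np.asarray(values, dtype=float)
    if mode == "presence":
        values = (values > 0).astype(float)
    return ExposureVector(values=values, mode=mode)
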