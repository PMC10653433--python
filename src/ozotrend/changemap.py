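"""From-to land-cover change encoding and district area summaries.

Two single-date 5-class land-cover maps (artificial surfaces A, cultivated
land C, forest F, grassland G, water W) are combined into a change map that
keeps only the 11 categories observed to be plausible: the 5 no-change
codes plus the 6 transitions among A, C and F (AC, AF, CA, CF, FA, FC).
Any other from-to pair is regarded as an artefact and becomes nodata; the
encoder counts what it rejected so the loss is auditable.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import CategoricalRaster, GridError

__all__ = [
    "CLASS_CODES",
    "CLASS_LABELS",
    "CHANGE_LEGEND",
    "ChangeEncoding",
    "encode_change",
    "area_proportions",
]

logger = logging.getLogger(__name__)

#: Land-cover class codes in canonical order.
CLASS_LABELS = ("A", "C", "F", "G", "W")
CLASS_CODES = {label: i + 1 for i, label in enumerate(CLASS_LABELS)}

#: Change-map legend: identity codes 1-5 in class order, then the six
#: whitelisted transitions in the order AC, AF, CA, CF, FA, FC.
_TRANSITIONS = ("AC", "AF", "CA", "CF", "FA", "FC")
CHANGE_LEGEND: dict[int, str] = {i + 1: lab for i, lab in enumerate(CLASS_LABELS)}
CHANGE_LEGEND.update({i + 6: lab for i, lab in enumerate(_TRANSITIONS)})

#: (from_label, to_label) -> change code, identity pairs included.
PAIR_TO_CODE: dict[tuple[str, str], int] = {
    (lab, lab): code for code, lab in list(CHANGE_LEGEND.items())[:5]
}
PAIR_TO_CODE.update(
    {(lab[0], lab[1]): code for code, lab in CHANGE_LEGEND.items() if len(lab) == 2}
)


@dataclass
class ChangeEncoding:
    """Result of :func:`encode_change`: the change raster plus a rejection report."""

    raster: CategoricalRaster
    n_rejected: int
    rejected_pairs: Counter


def encode_change(map1: CategoricalRaster, map2: CategoricalRaster) -> ChangeEncoding:
    """Encode two aligned single-date maps into the 11-category change map.

    Identity pairs map to the five no-change codes; the six whitelisted
    transitions map to their codes; every other transition becomes nodata
    and is tallied in the returned report.  Nodata in either input
    propagates.
    """
    if not map1.grid.aligned(map2.grid):
        raise GridError("land-cover maps are not on the same grid")
    for m in (map1, map2):
        bad = set(np.unique(m.codes[m.valid_mask]).tolist()) - set(CLASS_CODES.values())
        if bad:
            raise ValueError(f"unknown land-cover class codes: {sorted(bad)}")

    # lookup table indexed by (from_code, to_code); 0 = rejected
    lut = np.zeros((6, 6), dtype=np.int32)
    for (fr, to), code in PAIR_TO_CODE.items():
        lut[CLASS_CODES[fr], CLASS_CODES[to]] = code

    valid = map1.valid_mask & map2.valid_mask
    out = np.full(map1.codes.shape, map1.nodata, dtype=np.int32)
    coded = lut[map1.codes[valid], map2.codes[valid]]
    out[valid] = np.where(coded > 0, coded, map1.nodata)

    rejected = Counter()
    rej_mask = valid & (out == map1.nodata)
    if rej_mask.any():
        pairs = zip(map1.codes[rej_mask].tolist(), map2.codes[rej_mask].tolist())
        inv = {v: k for k, v in CLASS_CODES.items()}
        for fr, to in pairs:
            rejected[f"{inv[fr]}{inv[to]}"] += 1
        logger.info(
            "encode_change: rejected %d pixel(s) outside the 11-category whitelist: %s",
            sum(rejected.values()),
            dict(rejected),
        )
    raster = CategoricalRaster(map1.grid, out, map1.nodata, dict(CHANGE_LEGEND))
    return ChangeEncoding(raster, int(rej_mask.sum()), rejected)


def area_proportions(change: CategoricalRaster, zones: CategoricalRaster) -> pd.DataFrame:
    """Percent of each district's valid area in every change category.

    Rows are change-category labels, columns district ids; each column sums
    to 100 over the district's valid change pixels.  Districts with no
    valid change pixel yield zeros with a warning.
    """
    if not change.grid.aligned(zones.grid):
        raise GridError("change map and district zones are not on the same grid")
    labels = [CHANGE_LEGEND[c] for c in sorted(CHANGE_LEGEND)]
    districts = sorted(
        int(d) for d in np.unique(zones.codes[zones.valid_mask]).tolist()
    )
    table = pd.DataFrame(0.0, index=labels, columns=districts)
    for d in districts:
        in_d = (zones.codes == d) & change.valid_mask
        total = int(in_d.sum())
        if total == 0:
            warnings.warn(f"district {d} has no valid change pixels; zeros reported")
            continue
        codes, counts = np.unique(change.codes[in_d], return_counts=True)
        for code, cnt in zip(codes.tolist(), counts.tolist()):
            table.loc[CHANGE_LEGEND[code], d] = 100.0 * cnt / total
    return table
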