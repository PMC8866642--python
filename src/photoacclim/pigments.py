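"""Spectrophotometric pigment quantification from acetone extracts.

Chlorophyll a, chlorophyll b and total carotenoid concentrations are computed
from blank-corrected extract absorbances at 470, 645 and 662 nm (1-cm path)
with the Lichtenthaler coefficient set for 100% acetone:

    chla (ug/mL) = 11.24 A662 - 2.04 A645
    chlb (ug/mL) = 20.13 A645 - 4.19 A662
    car  (ug/mL) = (1000 A470 - 1.90 chla - 63.14 chlb) / 214

and standardized to leaf fresh weight: mg pigment g-1 FW =
ug/mL x extract volume (mL) / fresh weight (g) / 1000.  Coefficients live in
a single solvent-keyed table so another solvent set can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "EXTINCTION_COEFFS",
    "PigmentSample",
    "PigmentContent",
    "pigment_concentrations",
    "pigment_table",
]

# Solvent-specific chlorophyll / carotenoid extinction equation coefficients.
# Layout per solvent: chla = (c1*A662 + c2*A645); chlb = (c3*A645 + c4*A662);
# car = (1000*A470 - k1*chla - k2*chlb) / k3.
EXTINCTION_COEFFS = {
    "acetone_100": {
        "chla": (11.24, -2.04),
        "chlb": (20.13, -4.19),
        "car": (1.90, 63.14, 214.0),
    },
}


@dataclass(frozen=True)
class PigmentSample:
    """One shoot's extract absorbances plus the standardization inputs."""

    shoot_id: str
    a470: float
    a645: float
    a662: float
    extract_volume_ml: float = 10.0
    fresh_weight_g: float = 1.0

    def __post_init__(self) -> None:
        if min(self.a470, self.a645, self.a662) < 0:
            raise ParameterError("absorbances must be blank-corrected and >= 0")
        if self.fresh_weight_g <= 0:
            raise ParameterError(f"fresh weight must be > 0, got {self.fresh_weight_g}")
        if self.extract_volume_ml <= 0:
            raise ParameterError("extract volume must be > 0")


@dataclass(frozen=True)
class PigmentContent:
    """Pigment contents in mg pigment g-1 fresh weight; NaN where QC failed."""

    chla: float
    chlb: float
    carotenoids: float
    qc_flag: Optional[str] = None


def pigment_concentrations(
    sample: PigmentSample, solvent: str = "acetone_100"
) -> PigmentContent:
    """Convert extract absorbances to fresh-weight pigment contents.

    A negative intermediate concentration (possible with unusual absorbance
    ratios) marks that pigment as a QC failure: reported missing (NaN) with a
    flag rather than clipped.
    """
    coef = EXTINCTION_COEFFS[solvent]
    c1, c2 = coef["chla"]
    c3, c4 = coef["chlb"]
    k1, k2, k3 = coef["car"]
    chla = c1 * sample.a662 + c2 * sample.a645
    chlb = c3 * sample.a645 + c4 * sample.a662
    car = (1000.0 * sample.a470 - k1 * chla - k2 * chlb) / k3
    scale = sample.extract_volume_ml / sample.fresh_weight_g / 1000.0
    flags = [name for name, v in (("chla", chla), ("chlb", chlb), ("car", car)) if v < 0]
    return PigmentContent(
        chla=chla * scale if chla >= 0 else float("nan"),
        chlb=chlb * scale if chlb >= 0 else float("nan"),
        carotenoids=car * scale if car >= 0 else float("nan"),
        qc_flag="negative_" + "+".join(flags) if flags else None,
    )


def pigment_table(samples: pd.DataFrame, solvent: str = "acetone_100") -> pd.DataFrame:
    """Vectorized pigment computation over a pigment-sample table.

    Expects columns shoot_id, a470, a645, a662, extract_volume_ml,
    fresh_weight_g; returns shoot_id, chla_mg_gfw, chlb_mg_gfw, car_mg_gfw,
    qc_flag.
    """
    records = []
    for _, r in samples.iterrows():
        content = pigment_concentrations(
            PigmentSample(str(r["shoot_id"]), float(r["a470"]), float(r["a645"]),
                          float(r["a662"]), float(r["extract_volume_ml"]),
                          float(r["fresh_weight_g"])),
            solvent=solvent,
        )
        records.append({"shoot_id": str(r["shoot_id"]), "chla_mg_gfw": content.chla,
                        "chlb_mg_gfw": content.chlb, "car_mg_gfw": content.carotenoids,
                        "qc_flag": content.qc_flag})
    return pd.DataFrame.from_records(records)
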