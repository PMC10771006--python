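"""Weighted quantitative estimate of drug-likeness (QED).

QED scores a molecule as the weighted geometric mean of eight desirability
functions, each an asymmetric double sigmoid (ADS) fitted to the distribution
of that property among approved oral drugs (Bickerton et al., 2012):

    d(x) = a + b / (1 + exp(-(x - c + d/2)/e)) * [1 - 1/(1 + exp(-(x - c - d/2)/f))]

normalized by the function's maximum, with published parameters per property
(MW, ALOGP, HBA, HBD, PSA, ROTB, AROM, ALERTS).  The desirability transform
and the weighted geometric mean are implemented here; the eight raw property
values come from RDKit's property calculators.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

from rdkit.Chem import QED as _rdkit_qed_props

from .featurize import _as_mol

# Published ADS parameters (a, b, c, d, e, f, dmax) per property.
ADS_PARAMETERS: Dict[str, Tuple[float, float, float, float, float, float, float]] = {
    "MW": (2.817065973, 392.5754953, 290.7489764, 2.419764353,
           49.22325677, 65.37051707, 104.9805561),
    "ALOGP": (3.172690585, 137.8624751, 2.534937431, 4.581497897,
              0.822739154, 0.576295591, 131.3186604),
    "HBA": (2.948620388, 160.4605972, 3.615294657, 4.435986202,
            0.290141953, 1.300669958, 148.7763046),
    "HBD": (1.618662227, 1010.051101, 0.985094388, 0.000000001,
            0.713820843, 0.920922555, 258.1632616),
    "PSA": (1.876861559, 125.2232657, 62.90773554, 87.83366614,
            12.01999824, 28.51324732, 104.5686167),
    "ROTB": (0.01, 272.4121427, 2.55837997, 1.565547684,
             1.271567166, 2.758063707, 105.4420403),
    "AROM": (3.21778897, 957.7374108, 2.274627939, 0.000000001,
             1.317690384, 0.375760881, 312.337261),
    "ALERTS": (0.01, 1199.094025, -0.09002883, 0.000000001,
               0.185904477, 0.875193782, 417.725314),
}

#: weights of the published QED(weighted) variant (QED_w,mo)
QED_WEIGHTS: Dict[str, float] = {
    "MW": 0.66, "ALOGP": 0.46, "HBA": 0.05, "HBD": 0.61,
    "PSA": 0.06, "ROTB": 0.65, "AROM": 0.48, "ALERTS": 0.95,
}

PROPERTY_ORDER = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")


def desirability(name: str, x: float) -> float:
    """ADS desirability of property ``name`` at value ``x``, in (0, 1]."""
    a, b, c, d, e, f, dmax = ADS_PARAMETERS[name]
    val = a + b / (1.0 + math.exp(-(x - c + d / 2.0) / e)) * (
        1.0 - 1.0 / (1.0 + math.exp(-(x - c - d / 2.0) / f))
    )
    return val / dmax


def qed_properties(mol) -> Dict[str, float]:
    """The eight raw QED property values of a molecule."""
    props = _rdkit_qed_props.properties(_as_mol(mol))
    return {name: getattr(props, name) for name in PROPERTY_ORDER}


def qed_score(mol) -> float:
    """Weighted QED: exp of the weighted mean log-desirability, in (0, 1)."""
    props = qed_properties(mol)
    num = 0.0
    den = 0.0
    for name in PROPERTY_ORDER:
        w = QED_WEIGHTS[name]
        num += w * math.log(desirability(name, props[name]))
        den += w
    return math.exp(num / den)
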