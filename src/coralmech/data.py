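"""Built-in material constants for aragonite and its crystal interfaces.

Stiffness rows are experimental/computational literature values for
orthorhombic aragonite in Voigt notation (GPa), ordered
(C11, C22, C33, C44, C55, C66, C23, C31, C12).  Interfacial strengths are
(tensile, shear) pairs in MPa: the nacre pair is a lower-bound surrogate for
the aragonite needle interface; the micropillar pair is calibrated against
compression tests on coral skeleton micropillars.
"""

from __future__ import annotations

import numpy as np

from .tensor import ElasticTensor

__all__ = [
    "ARAGONITE_EXPERIMENTAL_MEDIAN",
    "ARAGONITE_EXPERIMENTAL_MIN",
    "ARAGONITE_EXPERIMENTAL_MAX",
    "NACRE_INTERFACE_MPA",
    "MICROPILLAR_INTERFACE_MPA",
    "NANO_POROSITY_DEFAULT",
    "ASPECT_RATIO_DEFAULT",
    "orthorhombic_voigt",
    "aragonite_median_stiffness",
]

#: (C11, C22, C33, C44, C55, C66, C23, C31, C12) in GPa
ARAGONITE_EXPERIMENTAL_MEDIAN = (171.1, 110.1, 85.0, 41.3, 25.6, 42.7, 18.9, 10.6, 60.3)
ARAGONITE_EXPERIMENTAL_MIN = (159.6, 87.0, 85.0, 39.3, 24.2, 40.2, 15.9, 2.0, 36.6)
ARAGONITE_EXPERIMENTAL_MAX = (228.8, 124.2, 98.4, 82.6, 51.2, 94.4, 41.9, 27.8, 102.4)

#: interfacial (tensile, shear) strengths, MPa
NACRE_INTERFACE_MPA = (158.33, 70.00)
MICROPILLAR_INTERFACE_MPA = (294.49, 130.20)

#: intrinsic nano-porosity of the pristine skeletal wall (organic-filled)
NANO_POROSITY_DEFAULT = 0.039
#: needle aspect ratio (long / short axis)
ASPECT_RATIO_DEFAULT = 10.0


def orthorhombic_voigt(constants: tuple[float, ...]) -> np.ndarray:
    """Assemble a 6x6 Voigt stiffness from the 9 orthorhombic constants
    ordered (C11, C22, C33, C44, C55, C66, C23, C31, C12)."""
    c11, c22, c33, c44, c55, c66, c23, c31, c12 = constants
    C = np.zeros((6, 6))
    C[0, 0], C[1, 1], C[2, 2] = c11, c22, c33
    C[3, 3], C[4, 4], C[5, 5] = c44, c55, c66
    C[1, 2] = C[2, 1] = c23
    C[0, 2] = C[2, 0] = c31
    C[0, 1] = C[1, 0] = c12
    return C


def aragonite_median_stiffness() -> ElasticTensor:
    """Median experimental aragonite stiffness (orthorhombic, GPa)."""
    return ElasticTensor.from_voigt(
        orthorhombic_voigt(ARAGONITE_EXPERIMENTAL_MEDIAN), "orthorhombic"
    )
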