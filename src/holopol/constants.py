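"""Sign and phase conventions, fixed in one place.

Every sign choice that is physically arbitrary but must be globally
consistent lives here:

* Illumination is left-circular with Jones vector ``(1, i)/sqrt(2)``,
  which corresponds to the Stokes vector ``(1, 0, 0, -1)`` under the
  Mueller convention used by the test oracles.
* A linear retarder with retardance ``delta`` and fast axis ``theta`` is
  ``R(theta) @ diag(exp(-i delta/2), exp(+i delta/2)) @ R(-theta)``.
  With circular illumination the detector channel at analyzer angle
  ``alpha`` then records ``1/2 (1 - sin(delta) sin(2 alpha - 2 theta))``
  times the squared amplitude transmittance.
* Forward angular-spectrum propagation over ``z > 0`` multiplies the
  spectrum by ``exp(-i 2 pi z / lambda * sqrt(1 - lambda^2 f^2))``;
  a constant (plane-wave) field therefore acquires the global phase
  ``exp(-i 2 pi z / lambda)``.
"""

import numpy as np

#: Jones vector of the circularly polarized illumination (unit intensity).
ILLUMINATION_JONES = np.array([1.0, 1.0j]) / np.sqrt(2.0)

#: Stokes vector equivalent to :data:`ILLUMINATION_JONES`.
ILLUMINATION_STOKES = np.array([1.0, 0.0, 0.0, -1.0])

#: Sign of the exponent in the forward angular-spectrum kernel.
FORWARD_KERNEL_SIGN = -1.0

#: Analyzer angles recorded by the polarization camera, in degrees.
ANALYZER_ANGLES_DEG = (0, 45, 90, 135)
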