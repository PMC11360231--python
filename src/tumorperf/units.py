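"""Unit conventions and physical defaults.

All spatial quantities are micrometres, time is seconds, pressure is
pascal.  The Darcy tensors are therefore um^2/(Pa s), wall hydraulic
coefficients um/(Pa s), and fluxes um^3/s.
"""

PA_PER_MMHG = 133.322
"""Pascal per mmHg."""

P_CAP_MMHG = 10.0
"""Effective intracapillary pressure (mmHg): hydrostatic + oncotic,
averaged over arteriolar/venular participation."""

P_CAP_PA = P_CAP_MMHG * PA_PER_MMHG  # 1333.22 Pa

H_CAP_DEFAULT = 1.57e-3
"""Capillary wall hydraulic coefficient, um/(Pa s), from a filtration
coefficient reduced to unit wall surface."""

K_TISSUE_DEFAULT = 1.0
"""Isotropic tissue Darcy coefficient, um^2/(Pa s).  Not an experimentally
pinned value; exposed everywhere as a parameter."""

MU_BLOOD_DEFAULT = 3.0e-3
"""Effective blood/plasma viscosity, Pa s."""

H_Z_DEFAULT = 1.0
"""Model thickness normal to the section plane, um."""
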