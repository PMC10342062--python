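"""Physical constants in the package's internal unit system (Å, ps, amu, kcal/mol, e)."""

#: Boltzmann constant, kcal/(mol K).
KB_KCAL = 0.0019872041

#: Coulomb constant, kcal Å / (mol e^2).
COULOMB_CONSTANT = 332.0636

#: Molecular volume of one water, cm^3.  Reproduces the diffusion permeability
#: pd = (Nw / 2T) * vw for printed bidirectional event counts at T = 300 ns.
VW_WATER_CM3 = 3.018e-23

#: sqrt(kcal/mol / (amu Å^2)) expressed in ps^-1; converts quasi-harmonic
#: frequencies from internal units. Uses amu*NA = 1 g/mol exactly.
OMEGA_TO_INV_PS = 20.4548283

#: Default simulation/analysis temperature, K.
DEFAULT_TEMPERATURE = 303.15

#: Membrane span Δz used for full-transit quantities, Å.
MEMBRANE_SPAN = 30.0

#: Picoseconds per nanosecond.
PS_PER_NS = 1000.0
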