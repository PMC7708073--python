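"""Physical constants and unit conventions.

Energies (dH, dG37) are in kcal/mol, entropies (dS) in cal/(mol K); the
factor of 1000 between them is applied in exactly two places
(:func:`hybridnn.predict.consistent_entropy` and
:func:`hybridnn.predict.predict_tm`).
"""

#: Gas constant, cal mol^-1 K^-1.
R_CAL = 1.987

#: 37 degC in kelvin; the reference temperature for dG37.
T37_K = 310.15

#: Additive offset between kelvin and degrees Celsius.
KELVIN_OFFSET = 273.15

#: Default total strand concentration (mol/L) at which melting temperatures
#: are reported for the bundled duplex table.
DEFAULT_CT = 8e-6
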