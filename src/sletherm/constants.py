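"""Physical constants shared across the package.

The gas constant is defined once here so that every module agrees on the
value used in regression slopes, SLE right-hand sides and ideal solubility.
"""

#: Molar gas constant, J mol^-1 K^-1 (CODATA, truncated to 6 significant figures).
GAS_CONSTANT: float = 8.31446

R = GAS_CONSTANT
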