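"""Physical constants (CODATA 2018), pinned for reproducibility."""

R_GAS = 8.314462618
"""Molar gas constant, J/(mol K)."""

FARADAY = 96485.33212
"""Faraday constant, C/mol."""

DEFAULT_TEMPERATURE_K = 293.15
"""Default bath temperature (20 degC) used when a recording does not state one."""
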