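"""Physical constants and package-wide defaults."""

#: Speed of light in vacuum, mm/ns (exact).
C_MM_PER_NS = 299.792458

#: Speed of light in vacuum, mm/ps.
C_MM_PER_PS = C_MM_PER_NS / 1000.0

#: Default refractive index of the liquid phantoms (water-like media).
DEFAULT_N = 1.33

#: Default source-detector separation on the phantom surface, mm.
DEFAULT_RHO = 30.0

#: Default static top-layer thickness in the two-layer scene, mm.
DEFAULT_TOP_THICKNESS = 10.0

#: Default TCSPC-like time axis: 4096 bins spanning 20 ns (~4.88 ps bins).
DEFAULT_N_BINS = 4096
DEFAULT_TIME_SPAN_PS = 20000.0

#: Default instrument response FWHM, ps (supercontinuum + hybrid-PMT chain).
DEFAULT_IRF_FWHM_PS = 550.0

#: Default photon budget: 1% of an 80 MHz repetition rate for 0.3 s.
DEFAULT_REP_RATE_HZ = 80e6
DEFAULT_COUNT_RATE_CAP = 0.01
DEFAULT_COLLECTION_TIME_S = 0.3
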