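# Optimized hiPSC-CM parameter set (biomarker-range optimization outcome).
# Values not listed here keep the model-family defaults.
name: paci2018-optimized
parameters:
  V_max_up: 0.5113        # mM/s, maximum SERCA uptake
  I_rel_max: 62.5434      # mM/s, maximum SR release rate
  RyR_a1: 0.05354         # uM, adaptation gate constant 1
  RyR_a2: 0.0488          # uM, adaptation gate constant 2
  RyR_a_half: 0.02427     # uM, adaptation gate half activation
  RyR_o_half: 0.01042     # uM, open gate half activation
  RyR_c_half: 0.00144     # uM, closed gate half activation
  I_NaCa_max: 3917.0463   # A/F, maximum Na+/Ca2+ exchanger current
  I_NaK_max: 2.6351       # A/F, maximum Na+/K+ pump current
  K_up: 3.1928e-4         # mM, SERCA half saturation
  I_leak_max: 4.7279e-4   # 1/s, maximum SR leak rate
  alpha: 2.5371           # -, I_NaCa outward-enhancement factor
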