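# Experimental biomarker ranges used to calibrate the model: spontaneous
# action-potential biomarkers from patch-clamp recordings and Ca2+-transient
# biomarkers from fluorescence imaging (mean, SD, cost-function weight).
# The `simulated` column is the published value of the optimized model and is
# used only by the reproduction harness, never by the cost function.
ranges:
  APA:           {mean: 104.0,  sd: 6.0,   weight: 1, units: mV,  simulated: 109.6}
  MDP:           {mean: -75.6,  sd: 6.6,   weight: 2, units: mV,  simulated: -75.8}
  CL:            {mean: 1700.0, sd: 547.7, weight: 2, units: ms,  simulated: 1549.3}
  Vmax:          {mean: 27.8,   sd: 26.3,  weight: 1, units: V/s, simulated: 24.8}
  APD10:         {mean: 74.1,   sd: 26.3,  weight: 1, units: ms,  simulated: 85.8}
  APD30:         {mean: 180.0,  sd: 58.6,  weight: 1, units: ms,  simulated: 241.8}
  APD90:         {mean: 414.7,  sd: 119.4, weight: 1, units: ms,  simulated: 379.8}
  Triangulation: {mean: 2.5,    sd: 1.1,   weight: 1, units: "-", simulated: 3.0}
  DURATION:      {mean: 804.5,  sd: 188.0, weight: 1, units: ms,  simulated: 617.8}
  TPEAK:         {mean: 270.4,  sd: 108.3, weight: 1, units: ms,  simulated: 165.9}
  RT1050:        {mean: 82.9,   sd: 50.5,  weight: 1, units: ms,  simulated: 47.7}
  RT1090:        {mean: 167.3,  sd: 69.8,  weight: 1, units: ms,  simulated: 106.0}
  DT9010:        {mean: 409.8,  sd: 100.1, weight: 1, units: ms,  simulated: 367.6}
  FREQ:          {mean: 0.70,   sd: 0.38,  weight: 1, units: Hz,  simulated: 0.65}
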