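# SYNTHETIC nominal PK parameter set -- NOT estimates from the rat study.
# Plausible literature-informed disposition values for a 180 g rat, used to
# drive simulations and the synthetic-data generator (volumes in L, rates in
# 1/h, clearances in L/h).  See docs/methods.md for the rationale.
carboplatin:
  k_el: 0.10        # 1/h   (CL ~ 9 mL/h; exposure sized to the observed
                    #        myelosuppression depth at the fitted kill slope)
  k_cp1: 0.3        # 1/h   shallow tissue distribution
  k_pc1: 0.15       # 1/h
  k_cp2: 0.05       # 1/h   slower distribution phase
  k_pc2: 0.05       # 1/h
  v_central: 0.09   # L     (~0.5 L/kg)
epo:
  k_el: 0.4         # 1/h   (CL ~ 3.6 mL/h, 20 mL/h/kg)
  v4: 0.009         # L     central (~plasma volume, 50 mL/kg)
  v5: 0.006         # L     peripheral
  q: 0.0015         # L/h   intercompartmental flow
romiplostim:
  ka: 0.08          # 1/h   first-order subcutaneous absorption (tmax ~ 1 d)
  cl: 0.01          # L/h   apparent clearance CL/F (Cmax ~ 10 ng/mL)
  v7: 0.15          # L     apparent central volume V/F
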