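# Pharmacodynamic parameter estimates of the CIAT rat hematopoiesis model
# (naive-pooled fit to the 9-arm rat study; units in comments).
kill: 0.06174       # mL/ug, slope of linear carboplatin inhibition
RBC0: 6.343         # 1e12 cells/L, baseline red blood cells
T_RET: 35.13        # h, mean residence time of reticulocytes
T_RBC: 297.3        # h, mean residence time of mature RBCs
PLT0: 1.009         # 1e12 cells/L, baseline platelets
T_MP: 106.0         # h, mean lifespan of megakaryocytes
T_PLT: 139.8        # h, mean lifespan of platelets
KE: 5.294e-3        # 1/h, HSPC -> BFU-E differentiation rate
MCH: 21.75          # pg/cell, mean corpuscular hemoglobin
Smax_RM1: 0.07491   # per (ng/mL), romiplostim slope on HSPC production
Smax_RM2: 0.08929   # per (ng/mL), romiplostim slope on HSPC -> MK
Smax_PLT1: 1.963    # per (1e12 cells/L), platelet feedback on HSPC production
Smax_PLT2: 2.768    # per (1e12 cells/L), platelet feedback on HSPC -> MK
Smax_EPO: 2.784     # dimensionless, maximal rHuEPO stimulus on HSPC -> BFU-E
SC50_E: 66.08       # mIU/mL, rHuEPO concentration at half-maximal stimulus
Ke0: 0.01669        # 1/h, effect-compartment equilibration rate
sigma_PLT1: 0.1657  # proportional residual SD, platelets
sigma_PLT2: 0.1103  # additive residual SD, platelets (1e12 cells/L)
sigma_RBC: 0.5616   # additive residual SD, RBC (1e12 cells/L)
sigma_HGB: 1.177    # additive residual SD, hemoglobin (g/dL)
# fixed structural constants (not estimated)
CF: 4000            # platelets produced per megakaryocyte
MCFU: 5             # BFU-E -> CFU-E amplification exponent (2^MCFU)
MNOR: 4             # CFU-E -> normoblast amplification exponent (2^MNOR)
T_EP: null          # h, precursor lifespan; null ties it to T_RET
N_EP: 1             # precursor transit sub-compartments
N_MK: 10            # megakaryocyte aging compartments
N_PLT: 10           # platelet aging compartments
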