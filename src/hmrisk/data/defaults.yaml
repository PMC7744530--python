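# Default study configuration: adult-receptor exposure parameters, per-metal
# toxicity constants (RfD mg/kg/day, SF (mg/kg/day)^-1, KP cm/h), drinking-water
# guideline limits (mg/L) and soil screening values (mg/kg), and the synthetic
# generator targets (per-metal mean/sd in mg/kg for soil, mg/L for water).
# Entries marked `synthetic: true` are plausible placeholders, not measured
# values (source table cell garbled or printed as zero).

exposure:
  ingr_soil: 100.0     # mg/day
  ingr_water: 2.0      # L/day
  inhr: 20.0           # m3/day
  ef: 365.0            # day/year
  ed: 55.0             # year
  bw: 70.0             # kg
  at: 20075.0          # day (= ed * 365)
  pef: 1.36e+9         # m3/kg
  sa: 5700.0           # cm2
  af: 0.07             # mg/(cm2 day)
  abs: 0.001           # dimensionless
  et: 0.58             # h/event

toxicity:
  Mn:
    rfd_ing: 4.6e-2
    rfd_inh: 1.43e-5
    rfd_derm: 1.84e-3
    guidelines: {WHO: 0.10, USEPA: 0.05, ECE: 0.05}
  Zn:
    rfd_ing: 3.0e-1
    rfd_inh: 3.0e-1
    rfd_derm: 6.0e-2
    kp: 0.006
    guidelines: {WHO: 3.00, USEPA: 5.00, MAC_soil: 300.0, TAV_soil: 1500.0}
  Cu:
    rfd_ing: 4.0e-2
    rfd_inh: 4.02e-2
    rfd_derm: 1.2e-2
    kp: 0.0001
    guidelines: {WHO: 2.00, USEPA: 1.30, ECE: 2.00, MAC_soil: 150.0, TAV_soil: 500.0}
  Cr:
    rfd_ing: 3.0e-3
    rfd_inh: 2.86e-5
    rfd_derm: 6.0e-5
    sf_ing: 0.5
    sf_inh: 0.42
    kp: 0.002
    guidelines: {WHO: 0.05, USEPA: 0.10, ECE: 0.05, MAC_soil: 200.0, TAV_soil: 450.0}
  Cd:
    rfd_ing: 1.0e-3
    rfd_inh: 5.7e-5
    rfd_derm: 5.0e-4
    sf_ing: 0.38
    sf_inh: 6.3
    guidelines: {WHO: 0.03, USEPA: 0.05, ECE: 0.05, MAC_soil: 5.0, TAV_soil: 20.0}
  Pb:
    rfd_ing: 3.5e-3
    rfd_inh: 3.25e-3
    rfd_derm: 5.25e-4
    sf_ing: 8.5e-3
    kp: 0.0001
    guidelines: {WHO: 0.01, USEPA: 0.015, ECE: 0.01, MAC_soil: 300.0, TAV_soil: 300.0}
  As:
    rfd_ing: 3.0e-3
    rfd_inh: 3.01e-4
    rfd_derm: 1.23e-4
    sf_ing: 1.5
    sf_inh: 0.151
    sf_derm: 3.66
    kp: 0.0001
    guidelines: {WHO: 0.01, USEPA: 0.01, ECE: 0.01, MAC_soil: 20.0, TAV_soil: 65.0}
  Fe:
    guidelines: {WHO: 0.30, USEPA: 0.30, ECE: 0.20}
  Mg: {}
  Ag: {}

# Carcinogens assessed for ILCR (known human carcinogens among the study metals).
carcinogens: [Pb, Cr, Cd, As]

synthetic:
  n_samples: {soil_site: 26, soil_control: 5, water_site: 5, water_control: 3}
  concentrations:
    soil:
      site:
        Mg: {mean: 53.70, sd: 8.97}
        Mn: {mean: 66.70, sd: 5.10}
        Ag: {mean: 3.50, sd: 1.60}
        Zn: {mean: 154.70, sd: 35.00}
        Cd: {mean: 10.05, sd: 1.17}
        Pb: {mean: 28.79, sd: 3.05}
        Cu: {mean: 22.60, sd: 3.29}
        Fe: {mean: 378.00, sd: 22.28}
        As: {mean: 42.48, sd: 3.84}
        Cr: {mean: 108.00, sd: 8.30}
      control:
        Mg: {mean: 4.30, sd: 2.76}
        Mn: {mean: 3.60, sd: 0.23}
        Ag: {mean: 0.80, sd: 1.00}
        Zn: {mean: 8.10, sd: 0.45}
        Cd: {mean: 3.80, sd: 0.28, synthetic: true}  # source SD cell garbled
        Pb: {mean: 1.94, sd: 0.37}
        Cu: {mean: 1.14, sd: 0.65}
        Fe: {mean: 22.46, sd: 9.83}
        As: {mean: 3.34, sd: 2.05}
        Cr: {mean: 5.80, sd: 3.48}
    water:
      site:
        Mg: {mean: 1.09, sd: 0.35}
        Mn: {mean: 0.07, sd: 0.01}
        Ag: {nondetect: true}
        Fe: {mean: 1.75, sd: 0.46}
        Zn: {mean: 2.15, sd: 0.63}
        Cd: {mean: 0.22, sd: 0.03}
        As: {mean: 1.66, sd: 0.67}
        Cr: {mean: 2.05, sd: 0.54}
        Pb: {mean: 1.67, sd: 0.30}
        Cu: {mean: 1.38, sd: 0.46}
      control:
        Mg: {mean: 0.42, sd: 0.11}
        Mn: {mean: 0.05, sd: 0.02}
        Ag: {nondetect: true}
        Fe: {mean: 0.05, sd: 0.02}
        Zn: {mean: 0.01, sd: 0.001, synthetic: true}  # source SD printed 0.00
        Cd: {mean: 0.01, sd: 0.001, synthetic: true}  # source SD printed 0.00
        As: {mean: 0.60, sd: 0.17}
        Cr: {mean: 0.62, sd: 0.36}
        Pb: {mean: 0.18, sd: 0.07}
        Cu: {mean: 0.21, sd: 0.01}
  depth_profile:
    grid_cm: [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
    plateau_cm: 50
    noise_cv: 0.05
    metals:
      Mg: {surface: 64.0, plateau: 51.5}
      Mn: {surface: 85.0, plateau: 75.0}
      Ag: {surface: 5.0, plateau: 5.0}
      Fe: {surface: 457.5, plateau: 350.0}
      Zn: {surface: 210.0, plateau: 30.0}
      Cd: {surface: 11.55, plateau: 4.5}
      As: {surface: 55.0, plateau: 22.0}
      Cr: {surface: 110.0, plateau: 23.5}
      Pb: {surface: 28.0, plateau: 8.5}
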