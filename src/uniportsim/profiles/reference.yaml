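# Benchmark profile: squaramide-type chloride carrier in a POPC
# large-unilamellar-vesicle dispersion (chloride-release assay).
# Units: lengths m, areas m^2 (footprints), densities m^-2, molar volumes
# L/mol, concentrations mol/L, volumes L, diffusion m^2/s, doses %mol-to-lipid.
carrier:
  P: 676.0            # water/lipid partition coefficient (logP 2.83)
  Kfm: 1480.0         # complex formation constant in the membrane, 1/M
  Kfs: 8.34e-9        # complex formation constant in solution, 1/M
  D: 1.5e-13          # free-carrier membrane diffusion coefficient, m^2/s
  Dc: 1.5e-13         # complex membrane diffusion coefficient, m^2/s
  Kag: 0.0            # solution aggregation constant, M^(1-z); 0 = off
  z: 5.0              # aggregation number (monomers per aggregate)
  area_H: null        # carrier footprint, m^2 (null disables coverage monitor)
  area_HG: null       # complex footprint, m^2
membrane:
  d: 2.0e-7           # vesicle outer diameter, m (200 nm extrusion)
  w: 2.85e-9          # bilayer hydrophobic thickness, m
  sigmaL: 1.3e+18     # lipid surface density, m^-2 (1.3 nm^-2)
  gammaL: 0.762       # POPC molar volume, L/mol
  gammaW: 0.018       # water molar volume, L/mol
  curvature_corrected: false
dispersion:
  lipid_conc: 3.7e-4  # total lipid, mol/L of sample (Vout/Vin ~ 349)
  Vtot: 1.0           # sample volume, L (results are intensive in Vtot)
guest_in: 0.489       # intravesicular anion concentration, mol/L
doses: [0.25, 0.5, 1.0, 2.0]   # carrier doses, %mol to total lipid
sim:
  t_total: 300.0      # simulated time, s
  ts_init: 1.0e-6     # initial/fixed time step, s
  ts_max: 1.0e-3      # adaptive-step cap, s
  dwell: 5.0          # sampling interval, s
  adaptive: true
  depletion_cap: 0.1  # max fraction of a donor pool moved per step
  coverage_warn: 1.0  # warn above this occupied-area fraction
  flux_area: bilayer  # area multiplying the flux: bilayer | leaflet
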