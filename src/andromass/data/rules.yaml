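# Fragmentation-fingerprint rule set for positive-mode in-source TOF spectra of
# labdane diterpene lactones and flavones. All masses in Da unless noted.
tolerances:
  exact_mda: 15.0        # exact tier: |observed loss - monoisotopic loss| <= 15 mDa
  nominal_da: 0.3        # nominal tier: |observed loss - round(monoisotopic loss)| <= 0.3 Da
losses:                  # neutral-loss vocabulary, monoisotopic masses
  H2O: 18.010565
  CH2: 14.015650
  CO: 27.994915
  CH3: 15.023475
  Glc: 162.052824        # anhydroglucosyl C6H10O5
  GlcA: 176.032088       # anhydroglucuronyl C6H8O6
  CH2O: 30.010565
max_water: 4             # composite losses: up to 4 x H2O plus at most one non-water unit
precedence:              # first matching class wins
  - bis_diterpene
  - diterpene_glucoside
  - diterpene_monomer
  - flavone_aglycone
  - flavone_O_glycoside
bis_diterpene:
  min_precursor_mz: 600.0
  min_water_count: 3               # a precursor-anchored edge carrying >= 3 waters
  monomer_fragments: [297.18, 269.18]   # dehydrated monomer ions diagnostic of dimers
  monomer_tol_da: 0.05
diterpene_glucoside:
  require_exact_glc: true          # the precursor->aglycone Glc edge must be exact-tier
diterpene_monomer:
  min_water_count: 2               # any sugar-free edge carrying >= 2 waters
flavone_aglycone:
  max_precursor_mz: 400.0          # CH3 / 2xCH3 (exact) or CO (either tier) loss
flavone_O_glycoside:
  aglycone_windows: [271.060, 287.055, 301.071, 315.087]
  window_tol_da: 0.010
  loose_tol_da: 0.1                # fallback tier, recorded in the evidence trail
residues:                          # sugar residue from precursor - aglycone
  hexosyl: 162.052824
  glucuronyl: 176.032088
quantifier_ions:                   # narrow-window quantitation targets (Da)
  andrographolide: 297.1798        # [M+H-3H2O]+  (alternate printed value: 297.1873)
  neoandrographolide: 319.2288     # [M+H-Glc]+   (alternate printed value: 319.2267)
  dehydroandrographolide: 297.1798 # [M+H-2H2O]+, isobaric with the andrographolide
                                   # quantifier; the two are resolved in time
                                   # (alternate printed value: 297.1873)
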