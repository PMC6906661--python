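# Culture screening metrics for the four packaged isolates: dry biomass
# (g per L of culture) and lipid content (percent of dry biomass), means
# and standard deviations as printed in the source study. G4-9's dry
# biomass was reported only graphically and is stored as missing.
sample_id,dry_biomass_g_per_L,lipid_content_pct,biomass_sd,lipid_sd
G4-3,1.34,62.63,0.05,8.32
G4-9,,89.10,,8.72
P2-15,0.18,57.48,0.04,3.19
P5-4,1.30,66.72,0.15,4.52
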