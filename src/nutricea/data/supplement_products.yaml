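# Commodity definitions for candidate nutrition supplements.
# Energy densities and prices follow published WFP/FAO figures (2012 USD).
# CSB: the published cost-per-ration ($15.66) implies a unit price of
# $0.481/kg even though the price is usually quoted as $0.48; 0.481 is
# stored so the ration cost reproduces to the cent.
products:
  - name: RUTF
    description: Ready-to-Use Therapeutic Food (lipid-based peanut paste)
    kcal_per_100g: 557
    price_per_kg: 2.18
    protein_pct_kcal: 10
    fat_pct_kcal: 59
  - name: CSB
    description: Corn-soya blend flour
    kcal_per_100g: 376
    price_per_kg: 0.481
    protein_pct_kcal: 18
    fat_pct_kcal: 17
  - name: maize
    description: Maize meal (yellow)
    kcal_per_100g: 366
    price_per_kg: 0.296
    protein_pct_kcal: 9
    fat_pct_kcal: 4
  - name: rice
    description: Rice (white)
    kcal_per_100g: 365
    price_per_kg: 0.540
    protein_pct_kcal: 8
    fat_pct_kcal: 2
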