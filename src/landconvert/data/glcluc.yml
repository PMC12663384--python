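# Harmonization table for GLAD GLCLUC 2000-2020, built against a condensed
# form of the published map strata (the product encodes vegetation height and
# wetland state in value ranges; this table enumerates one representative code
# per stratum group and should be regenerated from the full 0-255 strata when
# run against the real product).
dataset_id: glcluc
legend: "GLAD GLCLUC v2 strata, condensed to one code per stratum group"
classes:
  - {native_code: 1, native_label: "Terra firma short vegetation (semi-arid)",
     harmonized_code: GRASS_SHRUB}
  - {native_code: 2, native_label: "Terra firma dense short vegetation",
     harmonized_code: GRASS_SHRUB}
  - {native_code: 3, native_label: "Terra firma tree cover < 5 m",
     harmonized_code: GRASS_SHRUB,
     note: "Trees below the 5 m FAO forest height threshold count as short
            vegetation, not forestland."}
  - {native_code: 4, native_label: "Terra firma tree cover >= 5 m",
     harmonized_code: FOREST,
     note: "FAO height definition; >= 5 m tree cover is forestland."}
  - {native_code: 5, native_label: "Wetland short vegetation",
     harmonized_code: NONFOREST_WETLAND}
  - {native_code: 6, native_label: "Wetland tree cover < 5 m",
     harmonized_code: NONFOREST_WETLAND}
  - {native_code: 7, native_label: "Wetland tree cover >= 5 m (forested wetland)",
     harmonized_code: FOREST,
     note: "Forested wetlands belong to forestland under the height rule."}
  - {native_code: 8, native_label: "Open surface water present 20-79% of year",
     harmonized_code: NONFOREST_WETLAND}
  - {native_code: 9, native_label: "Open surface water (permanent)",
     harmonized_code: OTHER}
  - {native_code: 10, native_label: "Cropland",
     harmonized_code: CULTIVATED,
     note: "Herbaceous crops only; excludes tree crops and cultivated grassland."}
  - {native_code: 11, native_label: "Built-up",
     harmonized_code: OTHER}
  - {native_code: 12, native_label: "Snow/ice",
     harmonized_code: OTHER}
  - {native_code: 13, native_label: "Bare ground / sparse",
     harmonized_code: OTHER}
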