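# MIRCA2000 crop classification: 26 crop classes, up to 5 sub-crops each.
# Sub-crops represent distinct varieties or growing seasons of one crop class
# (spring vs winter cereals; paddy rice's up-to-three seasons plus upland and
# deep-water rice).
#
# group: rice | C3_cereal | C4_cereal | other
# perennial crops never take part in sequential (multi-harvest) systems.
version: 1
crops:
  - {crop_id: 1,  name: wheat,            group: C3_cereal, perennial: false, max_subcrops: 2}
  - {crop_id: 2,  name: maize,            group: C4_cereal, perennial: false, max_subcrops: 2}
  - {crop_id: 3,  name: rice,             group: rice,      perennial: false, max_subcrops: 5}
  - {crop_id: 4,  name: barley,           group: C3_cereal, perennial: false, max_subcrops: 2}
  - {crop_id: 5,  name: rye,              group: C3_cereal, perennial: false, max_subcrops: 2}
  - {crop_id: 6,  name: millet,           group: C4_cereal, perennial: false, max_subcrops: 1}
  - {crop_id: 7,  name: sorghum,          group: C4_cereal, perennial: false, max_subcrops: 1}
  - {crop_id: 8,  name: soybean,          group: other,     perennial: false, max_subcrops: 1}
  - {crop_id: 9,  name: sunflower,        group: other,     perennial: false, max_subcrops: 1}
  - {crop_id: 10, name: potato,           group: other,     perennial: false, max_subcrops: 1}
  - {crop_id: 11, name: cassava,          group: other,     perennial: false, max_subcrops: 2}
  - {crop_id: 12, name: sugar_cane,       group: other,     perennial: true,  max_subcrops: 1}
  - {crop_id: 13, name: sugar_beet,       group: other,     perennial: false, max_subcrops: 1}
  - {crop_id: 14, name: oil_palm,         group: other,     perennial: true,  max_subcrops: 1}
  - {crop_id: 15, name: rapeseed,         group: other,     perennial: false, max_subcrops: 1}
  - {crop_id: 16, name: groundnut,        group: other,     perennial: false, max_subcrops: 1}
  - {crop_id: 17, name: pulses,           group: other,     perennial: false, max_subcrops: 1}
  - {crop_id: 18, name: citrus,           group: other,     perennial: true,  max_subcrops: 1}
  - {crop_id: 19, name: date_palm,        group: other,     perennial: true,  max_subcrops: 1}
  - {crop_id: 20, name: grapes,           group: other,     perennial: true,  max_subcrops: 1}
  - {crop_id: 21, name: cotton,           group: other,     perennial: false, max_subcrops: 1}
  - {crop_id: 22, name: cocoa,            group: other,     perennial: true,  max_subcrops: 1}
  - {crop_id: 23, name: coffee,           group: other,     perennial: true,  max_subcrops: 1}
  - {crop_id: 24, name: others_perennial, group: other,     perennial: true,  max_subcrops: 1}
  - {crop_id: 25, name: fodder_grasses,   group: other,     perennial: true,  max_subcrops: 1}
  - {crop_id: 26, name: others_annual,    group: other,     perennial: false, max_subcrops: 5}
# Sub-crop semantics used by the default combination rules:
#   rice: subcrops 1-3 = paddy seasons, 4 = upland, 5 = deep water
#   wheat/maize/barley/rye/cassava: 1 = spring/main, 2 = winter/second variety
subcrop_semantics:
  rice_paddy_subcrops: [1, 2, 3]
  rice_upland_subcrop: 4
  rice_deepwater_subcrop: 5
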