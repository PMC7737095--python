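# FAO-AEZ length-of-growing-period (LGP) classes -> months.
#
# The FAO GeoNetwork LGP raster uses 16 classes, each 30 growing days wide
# except the first and the last three. This table reconstructs the
# class -> month conversion as floor(lower_bound_days / 30), capped at 12:
# year-round classes (14, 15) map to 12 months, the no-season classes
# (1 and the cold class 16) to 0 months. Override with a user table if the
# original conversion is available.
version: 1
classes:
  - {lgp_class: 1,  days_min: 0,   days_max: 0,   months: 0}   # no growing period
  - {lgp_class: 2,  days_min: 1,   days_max: 29,  months: 0}
  - {lgp_class: 3,  days_min: 30,  days_max: 59,  months: 1}
  - {lgp_class: 4,  days_min: 60,  days_max: 89,  months: 2}
  - {lgp_class: 5,  days_min: 90,  days_max: 119, months: 3}
  - {lgp_class: 6,  days_min: 120, days_max: 149, months: 4}
  - {lgp_class: 7,  days_min: 150, days_max: 179, months: 5}
  - {lgp_class: 8,  days_min: 180, days_max: 209, months: 6}
  - {lgp_class: 9,  days_min: 210, days_max: 239, months: 7}
  - {lgp_class: 10, days_min: 240, days_max: 269, months: 8}
  - {lgp_class: 11, days_min: 270, days_max: 299, months: 9}
  - {lgp_class: 12, days_min: 300, days_max: 329, months: 10}
  - {lgp_class: 13, days_min: 330, days_max: 364, months: 11}
  - {lgp_class: 14, days_min: 365, days_max: 365, months: 12}  # year-round
  - {lgp_class: 15, days_min: 365, days_max: 365, months: 12}  # year-round, humid
  - {lgp_class: 16, days_min: 0,   days_max: 0,   months: 0}   # too cold
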