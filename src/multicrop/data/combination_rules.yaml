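# Default permitted-combination rules for sequential cropping systems.
#
# This is a documented reconstruction of the technical-feasibility screen:
# the authoritative full table is not distributed with the upstream data, so
# the defaults below encode the three rules that are unambiguous on
# agronomic grounds and can be overridden from a user config:
#
#   1. Paddy rice is never sequenced with upland or deep-water rice (these
#      sub-crops are distinct production environments, not seasons).
#   2. Spring and winter varieties of the same cereal (wheat, maize, barley,
#      rye) are alternative varieties, not crops grown consecutively on the
#      same field: the pair is forbidden.
#   3. A crop may follow itself only when its sub-crops encode true multiple
#      seasons; by default only paddy rice (sub-crops 1-3).
#
# Perennial crops are excluded from multi-crop sequences structurally (see
# crops.yaml perennial flags); they always allocate as sole-crop systems.
version: 1
max_frequency: 3
# crops whose multi-season sub-crops may follow themselves in one cycle
same_crop_sequences_allowed: [3]
# symmetric forbidden pairs, each member as [crop_id, subcrop]
forbidden_pairs:
  # paddy rice (seasons 1-3) x upland rice
  - [[3, 1], [3, 4]]
  - [[3, 2], [3, 4]]
  - [[3, 3], [3, 4]]
  # paddy rice (seasons 1-3) x deep-water rice
  - [[3, 1], [3, 5]]
  - [[3, 2], [3, 5]]
  - [[3, 3], [3, 5]]
  # upland x deep-water rice
  - [[3, 4], [3, 5]]
  # spring x winter variety pairs of the same cereal
  - [[1, 1], [1, 2]]
  - [[2, 1], [2, 2]]
  - [[4, 1], [4, 2]]
  - [[5, 1], [5, 2]]
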