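"""Per-read metrics of the 29 target reads reported for the original
low-input carrier-sequencing demonstration run (5 *B. subtilis* detections,
18 contamination reads, 6 high-quality noise reads).  These printed values
serve as fixed inputs for summary-table recomputation and read-ID parsing
tests; DUST and quality scores are as printed at the source's precision.
"""

# (group, length_bp, mean_q, dust, channel, read_id)
TARGET_READS = [
    ("b_subtilis", 848, 11.7, 1.81, 69, "@channel_69_7447cdae-d9cc-4ce8-a7f5-b0602b74f485_template"),
    ("b_subtilis", 967, 11.7, 1.79, 200, "@channel_200_5dbffb79-af02-47d8-9b80-4bladaab20e8_template"),
    ("b_subtilis", 1559, 11.4, 1.85, 217, "@channel_217_4e9b9a3a-4d3f-4e85-9287-1607085867c5_template"),
    ("b_subtilis", 872, 10.0, 1.70, 381, "@channel_381_2ed7f3f3-ad20-4529-a63e-3af8639d1769_template"),
    ("b_subtilis", 1024, 11.2, 1.77, 500, "@channel_500_337c80cf-a4b9-403d-b0b3-71c443339b85_template"),
    ("contamination", 1556, 11.1, 2.08, 149, "@channel_149_9b525218-4812-46a9-b8ca-dd8e0cc326b6_template"),
    ("contamination", 561, 9.39, 2.09, 376, "@channel_376_9f4bcd65-7083-44ca-8ee1-b20c2b22df2e_template"),
    ("contamination", 527, 11.6, 1.59, 491, "@channel_491_2e67e9b2-8a67-41da-b4ca-d3ba18248350_template"),
    ("contamination", 595, 9.45, 1.93, 434, "@channel_434_cc74d4a9-b62f-4274-86d0-7d95370b6aba_template"),
    ("contamination", 627, 9.47, 1.95, 408, "@channel_408_44516fbc-2f75-46e6-870e-953c50ac6112_template"),
    ("contamination", 681, 11.4, 2.08, 13, "@channel_13_7738ebc8-3fdc-4cf2-9854-9b18b81ec924_template"),
    ("contamination", 496, 10.2, 3.12, 182, "@channel_182_5ed727df-dd19-481e-9820-f77f5c20d1e9_template"),
    ("contamination", 416, 12.1, 1.84, 227, "@channel_227_f3bf082a-827e-4557-a9db-20f662dfce22_template"),
    ("contamination", 989, 10.9, 2.02, 86, "@channel_86_e52fe73a-e4e7-45d5-9a72-71c473e18cb4_template"),
    ("contamination", 434, 11.9, 1.89, 98, "@channel_98_ac4b4212-6fd1-49cd-9042-38fb46a943ce_template"),
    ("contamination", 638, 11.7, 1.89, 101, "@channel_101_350b8de1-2288-4109-8b4a-a2210c0dd22e_template"),
    ("contamination", 569, 11.9, 2.29, 139, "@channel_139_239119b0-d638-4d8b-a2f2-f6ffb8aa0003_template"),
    ("contamination", 933, 9.35, 2.10, 368, "@channel_368_2edf50ed-1c62-42f0-ba32-0c05229ab9a2_template"),
    ("contamination", 554, 10.1, 1.99, 375, "@channel_375_97c139b2-fc1a-4a9f-96f8-4ce66247dbe2_template"),
    ("contamination", 661, 10.1, 2.38, 447, "@channel_447_472aece4-a8c2-4090-bd1a-0a0e6e35eec1_template"),
    ("contamination", 654, 11.6, 2.44, 290, "@channel_290_d2806fbe-0e0b-43f6-aa24-027e1f481630_template"),
    ("contamination", 445, 9.91, 1.76, 300, "@channel_300_a9532014-5520-48fd-9d3a-6f8f52c45eeb_template"),
    ("contamination", 442, 9.65, 2.00, 318, "@channel_318_b634ac5d-4a8d-401d-9dff-1314985e8fea_template"),
    ("hqnr", 581, 12.7, 2.44, 334, "@channel_334_1b63719e-2745-4eb8-afdf-7c5c19d94ec4_template"),
    ("hqnr", 422, 9.18, 5.99, 143, "@channel_143_a198d662-4306-42a5-bd53-caf57c7744fc_template"),
    ("hqnr", 267, 9.22, 2.21, 54, "@channel_54_103c006a-34c3-45ec-a521-ccbf7b461e5f_template"),
    ("hqnr", 865, 9.16, 1.85, 156, "@channel_156_54ea11b1-5323-4805-a7b8-53f0840d40de_template"),
    ("hqnr", 484, 11.7, 1.94, 166, "@channel_166_f5014250-90d6-4977-9307-3782e7e47a0d_template"),
    ("hqnr", 314, 9.42, 1.98, 241, "@channel_241_19270801-958b-418b-a5fc-7f8b02179efa_template"),
]


def lengths(group: str | None = None) -> list[int]:
    return [r[1] for r in TARGET_READS if group is None or r[0] == group]
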