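miR-223-3p
miR-32-5p
miR-10a-3p
miR-200c-3p
miR-342-5p
miR-206-3p
miR-133a-3p
miR-130b-3p
miR-369-3p
miR-9b-5p
miR-326-3p
miR-325-3p
miR-329-3p
miR-212-3p
miR-132-3p
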