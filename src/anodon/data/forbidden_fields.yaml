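# Default identifier-screening policy: field labels that must never appear in
# a donation payload.  Names are matched case-insensitively; patterns are
# Python regular expressions applied to the raw label.
forbidden_names:
  - name
  - first_name
  - last_name
  - full_name
  - email
  - phone
  - phone_number
  - address
  - street
  - zip_code
  - gps_latitude
  - gps_longitude
  - latitude
  - longitude
  - device_id
  - hardware_id
  - imei
  - serial_number
  - mac_address
  - ip_address
  - user_id
  - username
  - ecg_waveform
  - ecg
  - genome
  - dna
  - genotype
patterns:
  - "(?i)gps"
  - "(?i)latitude|longitude"
  - "(?i)e-?mail"
  - "(?i)phone"
  - "(?i)\\bimei\\b"
  - "(?i)mac[-_ ]?addr"
  - "(?i)ip[-_ ]?addr"
  - "(?i)device[-_ ]?id"
  - "(?i)\\becg\\b"
  - "(?i)genom|genetic|\\bdna\\b"
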