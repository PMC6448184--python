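# NUCC taxonomy code sets per supported provider type.
# Editable: NUCC revises codes; keys are provider types, values map
# code -> human-readable label.
certified_nurse_midwife:
  "367A00000X": "Advanced Practice Midwife"
  "176B00000X": "Midwife"
nurse_practitioner:
  "363L00000X": "Nurse Practitioner"
  "363LA2100X": "Nurse Practitioner, Acute Care"
  "363LA2200X": "Nurse Practitioner, Adult Health"
  "363LC0200X": "Nurse Practitioner, Critical Care Medicine"
  "363LC1500X": "Nurse Practitioner, Community Health"
  "363LF0000X": "Nurse Practitioner, Family"
  "363LG0600X": "Nurse Practitioner, Gerontology"
  "363LN0000X": "Nurse Practitioner, Neonatal"
  "363LN0005X": "Nurse Practitioner, Neonatal Critical Care"
  "363LP0200X": "Nurse Practitioner, Pediatrics"
  "363LP0222X": "Nurse Practitioner, Pediatric Critical Care"
  "363LP0808X": "Nurse Practitioner, Psychiatric/Mental Health"
  "363LP1700X": "Nurse Practitioner, Perinatal"
  "363LP2300X": "Nurse Practitioner, Primary Care"
  "363LS0200X": "Nurse Practitioner, School"
  "363LW0102X": "Nurse Practitioner, Women's Health"
  "363LX0001X": "Nurse Practitioner, Obstetrics & Gynecology"
  "363LX0106X": "Nurse Practitioner, Occupational Health"
dentist:
  "122300000X": "Dentist"
  "1223D0001X": "Dentist, Dental Public Health"
  "1223D0004X": "Dentist Anesthesiologist"
  "1223E0200X": "Dentist, Endodontics"
  "1223G0001X": "Dentist, General Practice"
  "1223P0106X": "Dentist, Oral & Maxillofacial Pathology"
  "1223P0221X": "Dentist, Pediatric Dentistry"
  "1223P0300X": "Dentist, Periodontics"
  "1223P0700X": "Dentist, Prosthodontics"
  "1223S0112X": "Dentist, Oral & Maxillofacial Surgery"
  "1223X0008X": "Dentist, Oral & Maxillofacial Radiology"
  "1223X0400X": "Dentist, Orthodontics & Dentofacial Orthopedics"
  "1223X2210X": "Dentist, Orofacial Pain"
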