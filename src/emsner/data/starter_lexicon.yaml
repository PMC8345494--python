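ECG:
  category: Clinical Procedure
  synonyms:
    - phrase: 12 lead ecg
    - phrase: ecg
    - phrase: e c g
      exact_only: true
    - phrase: ekg
    - phrase: ecg done
    - phrase: ecg 4 leads
    - phrase: cardiac monitoring
Stroke Assessment:
  category: Clinical Procedure
  synonyms:
    - phrase: facial droop
    - phrase: slurred speech
    - phrase: stroke assessment
    - phrase: fast positive
    - phrase: arm drift
Intravenous Cannulation:
  category: Clinical Procedure
  synonyms:
    - phrase: iv cannulation
    - phrase: intravenous cannulation
    - phrase: iv plug
      exact_only: true
    - phrase: iv access
Burns Cooling:
  category: Clinical Procedure
  synonyms:
    - phrase: burns cooling
    - phrase: cooling gel
    - phrase: burn shield
Valsalva Maneuver:
  category: Clinical Procedure
  synonyms:
    - phrase: valsalva maneuver
    - phrase: valsalva manoeuvre
    - phrase: valsalva
Bleeding:
  category: Clinical Finding
  synonyms:
    - phrase: bleeding
    - phrase: active bleeding
    - phrase: bleeding profusely
    - phrase: haemorrhage
    - phrase: hemorrhage
Signs Of Obvious Death:
  category: Clinical Finding
  synonyms:
    - phrase: signs of obvious death
    - phrase: rigor mortis
    - phrase: post mortem lividity
    - phrase: decomposition
Nitroglycerin (GTN):
  category: Medication
  synonyms:
    - phrase: gtn
    - phrase: gtn spray
    - phrase: s l gtn
      exact_only: true
    - phrase: nitroglycerin
    - phrase: glyceryl trinitrate
Aspirin:
  category: Medication
  synonyms:
    - phrase: aspirin
    - phrase: acetylsalicylic acid
Normal Saline:
  category: Medication
  synonyms:
    - phrase: normal saline
    - phrase: i v n s
      exact_only: true
    - phrase: iv ns 0 9%
      exact_only: true
    - phrase: sodium chloride 0 9%
Penthrox:
  category: Medication
  synonyms:
    - phrase: penthrox
    - phrase: methoxyflurane
Dextrose/Glucose:
  category: Medication
  synonyms:
    - phrase: dextrose
    - phrase: glucose
    - phrase: oral glucose
Adrenaline:
  category: Medication
  synonyms:
    - phrase: adrenaline
    - phrase: epinephrine
Diazepam:
  category: Medication
  synonyms:
    - phrase: diazepam
    - phrase: valium
Salbutamol:
  category: Medication
  synonyms:
    - phrase: salbutamol
    - phrase: salbutamol neb
    - phrase: ventolin
Tramadol:
  category: Medication
  synonyms:
    - phrase: tramadol
Syntometrine:
  category: Medication
  synonyms:
    - phrase: syntometrine
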