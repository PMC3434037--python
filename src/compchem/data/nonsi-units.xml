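<?xml version="1.0" encoding="UTF-8"?>
<unitList xmlns="http://www.xml-cml.org/schema"
          namespace="http://www.xml-cml.org/unit/nonSi/"
          title="Non-SI units (minimal bundled subset)">
  <unit id="hartree" term="hartree">
    <definition>Atomic unit of energy.</definition>
  </unit>
  <unit id="angstrom" term="angstrom"/>
  <unit id="cm-1" term="reciprocal centimetre">
    <definition>Wavenumber unit used for vibrational frequencies.</definition>
  </unit>
  <unit id="degree" term="degree of arc"/>
  <unit id="hartree.bohr-2" term="hartree per bohr squared"/>
  <unit id="atm" term="standard atmosphere"/>
  <unit id="electron" term="elementary charge"/>
</unitList>
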