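<?xml version="1.0" encoding="UTF-8"?>
<unitList xmlns="http://www.xml-cml.org/schema"
          namespace="http://www.xml-cml.org/unit/si/"
          title="SI units (minimal bundled subset)">
  <unit id="none" term="dimensionless">
    <definition>Explicit marker for dimensionless quantities.</definition>
  </unit>
  <unit id="k" term="kelvin"/>
  <unit id="pa" term="pascal"/>
  <unit id="s" term="second"/>
  <unit id="m" term="metre"/>
  <unit id="joule.mole-1.kelvin-1" term="joule per mole kelvin"/>
  <unit id="kilojoule.mole-1" term="kilojoule per mole"/>
</unitList>
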