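<?xml version="1.0" encoding="UTF-8"?>
<dictionary xmlns="http://www.xml-cml.org/schema"
            namespace="http://www.xml-cml.org/dictionary/compchem/"
            title="CompChem core dictionary (minimal bundled subset)">
  <entry id="jobList" term="job list">
    <definition>A wrapper for a series of successive computational job modules.</definition>
  </entry>
  <entry id="job" term="job">
    <definition>The smallest module fully describing one computational modeling unit.</definition>
  </entry>
  <entry id="initialization" term="model initialization">
    <definition>Model parameters and inputs of a computational job.</definition>
  </entry>
  <entry id="calculation" term="model calculation">
    <definition>A computation, optimization or iteration step of a job.</definition>
  </entry>
  <entry id="finalization" term="model finalization">
    <definition>Model outputs and results of a computational job.</definition>
  </entry>
  <entry id="environment" term="computing environment">
    <definition>Hardware, software and operating-system configuration metadata.</definition>
  </entry>
  <entry id="method" term="level of theory" dataType="xsd:string">
    <definition>Electronic-structure method, for example B3LYP.</definition>
  </entry>
  <entry id="basis" term="basis set" dataType="xsd:string">
    <definition>Gaussian basis set, for example 6-311+G(d,p).</definition>
  </entry>
  <entry id="jobtype" term="job type" dataType="xsd:string">
    <definition>Requested task of the job, for example opt or freq.</definition>
  </entry>
  <entry id="scfenergy" term="SCF energy" dataType="xsd:double">
    <definition>Converged self-consistent-field electronic energy.</definition>
  </entry>
  <entry id="frequencies" term="vibrational frequencies" dataType="xsd:double">
    <definition>Harmonic vibrational wavenumbers from a frequency analysis.</definition>
  </entry>
  <entry id="program" term="program name" dataType="xsd:string">
    <definition>Name of the quantum-chemistry program that produced the data.</definition>
  </entry>
  <entry id="programVersion" term="program version" dataType="xsd:string">
    <definition>Version string of the producing program.</definition>
  </entry>
  <entry id="startDateTime" term="start date and time" dataType="xsd:string">
    <definition>Timestamp at which the job started.</definition>
  </entry>
  <entry id="endDateTime" term="end date and time" dataType="xsd:string">
    <definition>Timestamp at which the job finished.</definition>
  </entry>
  <entry id="hessian" term="force constant matrix" dataType="xsd:double">
    <definition>Second derivatives of the energy with respect to nuclear displacements.</definition>
  </entry>
  <entry id="entropy" term="entropy" dataType="xsd:double">
    <definition>Standard molar entropy S.</definition>
  </entry>
  <entry id="enthalpy" term="thermal enthalpy" dataType="xsd:double">
    <definition>Thermal enthalpy H - H(0).</definition>
  </entry>
  <entry id="heatCapacityCp" term="heat capacity Cp" dataType="xsd:double">
    <definition>Constant-pressure molar heat capacity.</definition>
  </entry>
  <entry id="heatCapacityCv" term="heat capacity Cv" dataType="xsd:double">
    <definition>Constant-volume molar heat capacity.</definition>
  </entry>
</dictionary>
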