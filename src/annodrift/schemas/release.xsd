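<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for the annodrift versioned-release XML dialect: one dated
     knowledgebase snapshot of protein entries with function annotations,
     evidence records and publication references. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="peLevel">
    <xs:restriction base="xs:string">
      <xs:enumeration value="PE1"/>
      <xs:enumeration value="PE2"/>
      <xs:enumeration value="PE3"/>
      <xs:enumeration value="PE4"/>
      <xs:enumeration value="PE5"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="category">
    <xs:restriction base="xs:string">
      <xs:enumeration value="catalytic-activity"/>
      <xs:enumeration value="function-info"/>
      <xs:enumeration value="go-biological-process"/>
      <xs:enumeration value="go-molecular-function"/>
      <xs:enumeration value="pathway"/>
      <xs:enumeration value="transport-activity"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="evidenceKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="direct-assay"/>
      <xs:enumeration value="physical-interaction"/>
      <xs:enumeration value="sequence-similarity"/>
      <xs:enumeration value="curator-inference"/>
      <xs:enumeration value="author-statement"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="granularity">
    <xs:restriction base="xs:string">
      <xs:enumeration value="day"/>
      <xs:enumeration value="year"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="release">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="entry" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="annotation" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="evidence" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="publication" minOccurs="0">
                            <xs:complexType>
                              <xs:attribute name="id" type="xs:string" use="required"/>
                              <xs:attribute name="date" type="xs:string" use="required"/>
                              <xs:attribute name="granularity" type="granularity" default="day"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                        <xs:attribute name="kind" type="evidenceKind" use="required"/>
                        <xs:attribute name="negative" type="xs:boolean" default="false"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="category" type="category" use="required"/>
                  <xs:attribute name="term-id" type="xs:string"/>
                  <xs:attribute name="term-label" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="accession" type="xs:string" use="required"/>
            <xs:attribute name="chromosome" type="xs:string" default="unknown"/>
            <xs:attribute name="existence-level" type="peLevel" default="PE1"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="date" type="xs:date" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
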