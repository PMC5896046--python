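<?xml version='1.0' encoding='UTF-8'?>
<entrySet xmlns="http://psi.hupo.org/mi/mif300" level="3" version="0" minorVersion="0">
  <entry>
    <source>
      <names>
        <shortLabel>psimif</shortLabel>
        <fullName>psimif fixture generator</fullName>
      </names>
    </source>
    <experimentList>
      <experimentDescription id="1">
        <names>
          <shortLabel>mutant affinity</shortLabel>
        </names>
        <bibref>
          <xref>
            <primaryRef db="pubmed" id="9100002" refType="primary-reference"/>
          </xref>
        </bibref>
        <hostOrganismList>
          <hostOrganism ncbiTaxId="9606">
            <names>
              <shortLabel>human</shortLabel>
            </names>
          </hostOrganism>
        </hostOrganismList>
        <interactionDetectionMethod>
          <names>
            <shortLabel>x-ray crystallography</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0114" refType="identity"/>
          </xref>
        </interactionDetectionMethod>
        <participantIdentificationMethod>
          <names>
            <shortLabel>predetermined participant</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0396" refType="identity"/>
          </xref>
        </participantIdentificationMethod>
      </experimentDescription>
    </experimentList>
    <interactorList>
      <interactor id="2">
        <names>
          <shortLabel>kin2</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="prot-0002" refType="identity"/>
        </xref>
        <interactorType>
          <names>
            <shortLabel>protein</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0326" refType="identity"/>
          </xref>
        </interactorType>
        <organism ncbiTaxId="9606">
          <names>
            <shortLabel>human</shortLabel>
          </names>
        </organism>
      </interactor>
      <interactor id="3">
        <names>
          <shortLabel>sub7</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="prot-0003" refType="identity"/>
        </xref>
        <interactorType>
          <names>
            <shortLabel>protein</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0326" refType="identity"/>
          </xref>
        </interactorType>
        <organism ncbiTaxId="9606">
          <names>
            <shortLabel>human</shortLabel>
          </names>
        </organism>
      </interactor>
    </interactorList>
    <interactionList>
      <interaction id="4">
        <experimentList>
          <experimentRef>1</experimentRef>
        </experimentList>
        <participantList>
          <participant id="5">
            <interactorRef>2</interactorRef>
            <biologicalRole>
              <names>
                <shortLabel>unspecified role</shortLabel>
              </names>
              <xref>
                <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
              </xref>
            </biologicalRole>
            <experimentalRoleList>
              <experimentalRole>
                <names>
                  <shortLabel>bait</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0496" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
            <featureList>
              <feature id="6">
                <names>
                  <shortLabel>r128a</shortLabel>
                </names>
                <featureType>
                  <names>
                    <shortLabel>mutation</shortLabel>
                  </names>
                  <xref>
                    <primaryRef db="psi-mi" id="MI:0118" refType="identity"/>
                  </xref>
                </featureType>
                <featureRangeList>
                  <featureRange>
                    <startStatus>
                      <names>
                        <shortLabel>certain</shortLabel>
                      </names>
                      <xref>
                        <primaryRef db="psi-mi" id="MI:0335" refType="identity"/>
                      </xref>
                    </startStatus>
                    <begin position="128"/>
                    <endStatus>
                      <names>
                        <shortLabel>certain</shortLabel>
                      </names>
                      <xref>
                        <primaryRef db="psi-mi" id="MI:0335" refType="identity"/>
                      </xref>
                    </endStatus>
                    <end position="128"/>
                    <resultingSequence>
                      <originalSequence>R</originalSequence>
                      <newSequence>A</newSequence>
                    </resultingSequence>
                  </featureRange>
                </featureRangeList>
              </feature>
            </featureList>
          </participant>
          <participant id="7">
            <interactorRef>3</interactorRef>
            <biologicalRole>
              <names>
                <shortLabel>unspecified role</shortLabel>
              </names>
              <xref>
                <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
              </xref>
            </biologicalRole>
            <experimentalRoleList>
              <experimentalRole>
                <names>
                  <shortLabel>prey</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0498" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
          </participant>
        </participantList>
        <interactionType>
          <names>
            <shortLabel>physical association</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0915" refType="identity"/>
          </xref>
        </interactionType>
      </interaction>
    </interactionList>
  </entry>
</entrySet>
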