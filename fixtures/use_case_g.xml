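<?xml version='1.0' encoding='UTF-8'?>
<entrySet xmlns="http://psi.hupo.org/mi/mif300" level="3" version="0" minorVersion="0">
  <entry>
    <source>
      <names>
        <shortLabel>psimif</shortLabel>
        <fullName>psimif fixture generator</fullName>
      </names>
    </source>
    <interactorList>
      <interactor id="1">
        <names>
          <shortLabel>cplx-core</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="prot-0010" refType="identity"/>
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
      <interactor id="2">
        <names>
          <shortLabel>cplx-ring</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="prot-0011" refType="identity"/>
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
      <abstractInteraction id="3">
        <names>
          <shortLabel>core-ring complex</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="cplx-0001" refType="identity"/>
        </xref>
        <interactorType>
          <names>
            <shortLabel>complex</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0314" refType="identity"/>
          </xref>
        </interactorType>
        <interactionType>
          <names>
            <shortLabel>physical association</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0915" refType="identity"/>
          </xref>
        </interactionType>
        <organism ncbiTaxId="9606">
          <names>
            <shortLabel>human</shortLabel>
          </names>
        </organism>
        <participantList>
          <participant id="4">
            <interactorRef>1</interactorRef>
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
                  <shortLabel>unspecified role</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
            <featureList>
              <feature id="5">
                <names>
                  <shortLabel>core binding region</shortLabel>
                </names>
                <featureType>
                  <names>
                    <shortLabel>binding-associated region</shortLabel>
                  </names>
                  <xref>
                    <primaryRef db="psi-mi" id="MI:0117" refType="identity"/>
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
                    <begin position="10"/>
                    <endStatus>
                      <names>
                        <shortLabel>certain</shortLabel>
                      </names>
                      <xref>
                        <primaryRef db="psi-mi" id="MI:0335" refType="identity"/>
                      </xref>
                    </endStatus>
                    <end position="40"/>
                  </featureRange>
                </featureRangeList>
              </feature>
            </featureList>
            <stoichiometry value="1"/>
          </participant>
          <participant id="6">
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
                  <shortLabel>unspecified role</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
            <featureList>
              <feature id="7">
                <names>
                  <shortLabel>ring binding region</shortLabel>
                </names>
                <featureType>
                  <names>
                    <shortLabel>binding-associated region</shortLabel>
                  </names>
                  <xref>
                    <primaryRef db="psi-mi" id="MI:0117" refType="identity"/>
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
                    <begin position="100"/>
                    <endStatus>
                      <names>
                        <shortLabel>certain</shortLabel>
                      </names>
                      <xref>
                        <primaryRef db="psi-mi" id="MI:0335" refType="identity"/>
                      </xref>
                    </endStatus>
                    <end position="140"/>
                  </featureRange>
                </featureRangeList>
              </feature>
            </featureList>
            <stoichiometry value="4"/>
          </participant>
        </participantList>
        <bindingFeaturesList>
          <bindingFeatures>
            <participantFeatureRef>5</participantFeatureRef>
            <participantFeatureRef>7</participantFeatureRef>
          </bindingFeatures>
        </bindingFeaturesList>
        <evidenceType>
          <names>
            <shortLabel>inferred from physical evidence</shortLabel>
          </names>
        </evidenceType>
      </abstractInteraction>
    </interactionList>
  </entry>
</entrySet>
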